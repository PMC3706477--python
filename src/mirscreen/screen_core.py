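"""Per-plate normalization of dual-luciferase readings and fold changes.

A dual-luciferase reporter well yields two readings: Renilla luciferase
(fused to the 3'UTR under test, i.e. the signal channel) and firefly
luciferase (co-expressed transfection control). The measurement for a well
is the Renilla/firefly ratio. Each 96-well plate carries its own
empty-miRNA-vector control wells; every ratio on a plate is divided by the
mean control ratio of that plate, so the control level is 1 by construction
and a normalized ratio < 1 means the miRNA represses the reporter.

Data flow is DataFrame-centric: wells in, one row per well out, then
per-interaction replicate vectors pooled across plates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, PlateQCError

logger = logging.getLogger(__name__)

#: canonical plate-table columns
WELL_COLUMNS = [
    "plate_id",
    "well_id",
    "role",
    "mirna_id",
    "reporter_id",
    "replicate",
    "firefly_rlu",
    "renilla_rlu",
]

ROLE_TEST = "test"
ROLE_CONTROL = "control"

#: mirna_id carried by empty-vector control wells
CONTROL_MIRNA_ID = "empty_vector"


@dataclass(frozen=True)
class WellRecord:
    """One well's raw readings plus plate/role/replicate metadata."""

    plate_id: str
    well_id: str
    role: str
    mirna_id: str
    reporter_id: str
    replicate: int
    firefly_rlu: float
    renilla_rlu: float


def well_ratio(firefly_rlu: float, renilla_rlu: float) -> float:
    """Raw Renilla/firefly ratio for one well.

    Raises
    ------
    InputError
        If the firefly (normalizer) reading is not positive.
    """
    if not firefly_rlu > 0:
        raise InputError(f"firefly_rlu must be positive, got {firefly_rlu!r}")
    if renilla_rlu < 0:
        raise InputError(f"renilla_rlu must be non-negative, got {renilla_rlu!r}")
    return renilla_rlu / firefly_rlu


def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize one plate's raw ratios to its own control-well mean.

    Parameters
    ----------
    wells
        Rows of one plate in the canonical well schema (see ``WELL_COLUMNS``).

    Returns
    -------
    DataFrame with the input metadata plus ``raw_ratio`` and
    ``normalized_ratio`` columns. The mean normalized ratio of the control
    wells is exactly 1.

    Raises
    ------
    PlateQCError
        Fewer than 2 control wells, or the control mean ratio is 0.
    """
    if wells.empty:
        raise PlateQCError("empty plate")
    plate_ids = wells["plate_id"].unique()
    if len(plate_ids) != 1:
        raise PlateQCError(f"normalize_plate got {len(plate_ids)} plates: {plate_ids!r}")

    raw = np.array(
        [well_ratio(f, r) for f, r in zip(wells["firefly_rlu"], wells["renilla_rlu"])]
    )
    is_control = (wells["role"] == ROLE_CONTROL).to_numpy()
    n_controls = int(is_control.sum())
    if n_controls < 2:
        raise PlateQCError(
            f"plate {plate_ids[0]!r} has {n_controls} control wells; need >= 2"
        )
    control_mean = raw[is_control].mean()
    if control_mean <= 0:
        raise PlateQCError(f"plate {plate_ids[0]!r} control mean ratio is {control_mean}")

    out = wells.copy()
    out["raw_ratio"] = raw
    out["normalized_ratio"] = raw / control_mean
    return out


def normalize_screen(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize every plate in a screen independently (plate-wise apply)."""
    parts = [
        normalize_plate(group) for _, group in wells.groupby("plate_id", sort=False)
    ]
    if not parts:
        return wells.assign(raw_ratio=[], normalized_ratio=[])
    return pd.concat(parts, ignore_index=True)


def integrate_plates(
    measurements: pd.DataFrame, min_replicates: int = 2
) -> dict[tuple[str, str], pd.DataFrame]:
    """Pool normalized replicates of each interaction across plates.

    Replicates for the same (miRNA, reporter) interaction measured on
    different plates are concatenated — never averaged — so the replicate
    count available to the t-test is preserved. Plate provenance is retained
    in each returned frame.

    Interactions with fewer than ``min_replicates`` test wells after pooling
    are excluded and logged.

    Returns
    -------
    Mapping (mirna_id, reporter_id) -> DataFrame of that interaction's test
    wells (normalized), in input order.
    """
    out: dict[tuple[str, str], pd.DataFrame] = {}
    tests = measurements[measurements["role"] == ROLE_TEST]
    for key, group in tests.groupby(["mirna_id", "reporter_id"], sort=False):
        if len(group) < min_replicates:
            logger.warning(
                "interaction %s excluded: %d replicate(s) < %d",
                key,
                len(group),
                min_replicates,
            )
            continue
        out[key] = group.reset_index(drop=True)
    return out


def control_vector(measurements: pd.DataFrame, plate_ids) -> np.ndarray:
    """Normalized control-well ratios from the given plates, pooled."""
    mask = (measurements["role"] == ROLE_CONTROL) & measurements["plate_id"].isin(
        set(plate_ids)
    )
    return measurements.loc[mask, "normalized_ratio"].to_numpy()


def fold_change(ratios) -> float:
    """Mean normalized ratio of an interaction's replicates.

    Controls are 1 by plate normalization, so this is the fold change
    relative to the empty-vector control; < 1 means repression.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise InputError("fold_change of an empty replicate vector")
    return float(ratios.mean())


def fold_change_ecdf(values) -> pd.DataFrame:
    """Empirical cumulative distribution of fold changes.

    Returns a DataFrame with ``fold_change`` sorted ascending and
    ``cumulative_fraction`` rising from 1/n to 1 — the cumulative curve
    summarizing repression across all interactions of a screen.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise InputError("ECDF of an empty vector")
    frac = np.arange(1, values.size + 1) / values.size
    return pd.DataFrame({"fold_change": values, "cumulative_fraction": frac})


def ddct_fold(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change by the delta-delta-Ct qPCR method.

    fold = 2**-((Ct_target,treated - Ct_ref,treated)
                - (Ct_target,control - Ct_ref,control))
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(np.isfinite(c) for c in cts):
        raise InputError(f"non-finite Ct value in {cts!r}")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))
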