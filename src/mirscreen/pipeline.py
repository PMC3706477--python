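"""End-to-end workflows: normalize -> call hits -> benchmark -> MRE profile.

Two workflows are supported, mirroring how such screens are run:

* predicted-set validation — assay only program-predicted interactions,
  then benchmark each program's precision against the calls;
* genome-wide screen — assay every library miRNA against a reporter and
  split the positive rate by predicted / unpredicted status.

``run_pipeline`` chains the stages on file inputs and writes a manifest;
the per-stage functions operate on in-memory frames and are what the
library API and tests use.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import hit_stats, io, mre_conservation as mre, prediction_eval, screen_core
from .errors import MirscreenError, StageError

logger = logging.getLogger(__name__)


def analyze_screen(
    wells: pd.DataFrame, config: io.RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize a well table and call hits.

    Returns (normalized well table, hit table). Each interaction's test
    replicates are pooled across plates and compared against the pooled
    normalized control ratios of the same plates.
    """
    config = config or io.RunConfig()
    normalized = screen_core.normalize_screen(wells)
    interactions = screen_core.integrate_plates(normalized)
    results = []
    for (mirna_id, reporter_id), group in interactions.items():
        controls = screen_core.control_vector(normalized, group["plate_id"].unique())
        results.append(
            hit_stats.score_interaction(
                mirna_id,
                reporter_id,
                group["normalized_ratio"].to_numpy(),
                controls,
                plate_ids=group["plate_id"].unique(),
                alpha=config.alpha,
                strong_cut=config.ssmd_strong,
                extreme_cut=config.ssmd_extreme,
            )
        )
    hits = hit_stats.call_hits(results, alpha=config.alpha)
    return normalized, hits


def screen_positive_rates(
    hits: pd.DataFrame, predicted_pairs: set[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Overall / predicted / unpredicted positive rates of a screen.

    ``predicted_pairs`` is the set of (mirna_id, reporter_id) pairs any
    prediction program proposed; omit it to get the overall rate only.
    """
    rows = [
        (
            "overall",
            int(hits["positive"].sum()),
            len(hits),
        )
    ]
    if predicted_pairs is not None:
        keys = list(zip(hits["mirna_id"], hits["reporter_id"]))
        is_pred = np.array([k in predicted_pairs for k in keys])
        for name, mask in (("predicted", is_pred), ("unpredicted", ~is_pred)):
            if mask.any():
                rows.append(
                    (name, int(hits.loc[mask, "positive"].sum()), int(mask.sum()))
                )
    return pd.DataFrame(
        {
            "subset": [r[0] for r in rows],
            "positive": [r[1] for r in rows],
            "tested": [r[2] for r in rows],
            "rate_percent": [
                hit_stats.positive_rate(r[1], r[2]) for r in rows
            ],
        }
    )


def mre_profile(
    utrs: dict[str, str],
    mirnas: dict[str, str],
    tracks: dict[str, np.ndarray],
    hits: pd.DataFrame,
    config: io.RunConfig | None = None,
    group_mode: str = "ssmd3",
    background: dict[str, str] | None = None,
    background_tracks: dict[str, np.ndarray] | None = None,
    n_random: int = 203,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Scan tested interactions for seed sites and profile conservation.

    For every tested (miRNA, reporter/UTR) pair the UTR is scanned for the
    exact seed complement; each site becomes a flanked window carrying the
    track scores and the interaction's group label. A random group is
    sampled from ``background`` sequences when given (defaulting to the
    UTRs themselves as background).

    Returns (window table, positional profile table, Wilcoxon p-values for
    positive-vs-negative and positive-vs-random window means).
    """
    config = config or io.RunConfig()
    groups = mre.assign_groups(hits, mode=group_mode, ssmd_cut=config.ssmd_extreme)

    windows: list[mre.MREWindow] = []
    dropped = 0
    for (mirna_id, utr_id), group in groups.items():
        if mirna_id not in mirnas or utr_id not in utrs:
            continue
        motif = mre.seed_complement(mirnas[mirna_id], config.seed_span)
        for site in mre.seed_site_scan(utrs[utr_id], motif):
            w = mre.extract_window(
                utrs[utr_id],
                site,
                gene_id=utr_id,
                mirna_id=mirna_id,
                flank5=config.flank5,
                flank3=config.flank3,
                scores=tracks.get(utr_id),
                group=group,
            )
            if w is None:
                dropped += 1
            else:
                windows.append(w)
    if dropped:
        logger.warning("%d boundary-violating window(s) dropped", dropped)

    window_len = config.flank5 + (config.seed_span[1] - config.seed_span[0] + 1) + config.flank3
    if background is None:
        background, background_tracks = utrs, tracks
    windows += mre.sample_random_windows(
        background,
        background_tracks if background_tracks is not None else tracks,
        n_windows=n_random,
        window_length=window_len,
        rng_seed=config.rng_seed,
    )

    rows = []
    for w in windows:
        mean = mre.window_mean_score(w)
        if mean is None:
            continue
        rows.append(
            (w.gene_id, w.mirna_id, w.window_start, w.window_end, w.site_start,
             w.site_end, w.group, mean)
        )
    window_table = pd.DataFrame(
        rows,
        columns=["seq_id", "mirna_id", "window_start", "window_end", "site_start",
                 "site_end", "group", "mean_score"],
    )

    profile_cols: dict[str, np.ndarray] = {}
    labels = None
    for grp in (mre.GROUP_POSITIVE, mre.GROUP_NEGATIVE, mre.GROUP_RANDOM):
        members = [w for w in windows if w.group == grp]
        if members:
            labels, means = mre.positional_profile(members)
            profile_cols[f"mean_{grp}"] = means
    profile = pd.DataFrame({"position_label": labels, **profile_cols})

    tests: dict[str, float] = {}
    pos = window_table.loc[window_table["group"] == mre.GROUP_POSITIVE, "mean_score"]
    for other in (mre.GROUP_NEGATIVE, mre.GROUP_RANDOM):
        vals = window_table.loc[window_table["group"] == other, "mean_score"]
        if len(pos) and len(vals):
            _, p = mre.wilcoxon_rank_sum(pos, vals)
            tests[f"positive_vs_{other}_p"] = p
    return window_table, profile, tests


def run_pipeline(
    config: io.RunConfig,
    plates_path,
    out_dir,
    predictions_path=None,
    utrs_path=None,
    mirnas_path=None,
    track_path=None,
    group_mode: str = "ssmd3",
) -> dict[str, Path]:
    """File-to-file umbrella: every produced artifact lands in ``out_dir``
    and is listed, with a checksum, in ``manifest.json``.

    Stage failures abort with a stage-tagged ``StageError``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def _stage(name, fn):
        try:
            return fn()
        except MirscreenError as exc:
            raise StageError(f"[{name}] {exc}") from exc

    wells = _stage("read-plates", lambda: io.read_plate_table(plates_path))
    normalized, hits = _stage("normalize", lambda: analyze_screen(wells, config))
    outputs["normalized"] = out_dir / "normalized.tsv"
    io.write_table(normalized, outputs["normalized"])
    outputs["hits"] = out_dir / "hits.tsv"
    io.write_table(hits, outputs["hits"])

    fc = hits["fold_change"].to_numpy()
    if fc.size:
        outputs["fold_change_ecdf"] = out_dir / "fold_change_ecdf.tsv"
        io.write_table(screen_core.fold_change_ecdf(fc), outputs["fold_change_ecdf"])
    outputs["dual_flashlight"] = out_dir / "dual_flashlight.tsv"
    io.write_table(
        hits[["mirna_id", "reporter_id", "ssmd", "fold_change", "ssmd_class"]],
        outputs["dual_flashlight"],
    )

    if predictions_path is not None:
        counts = _stage("read-predictions", lambda: io.read_table(predictions_path))
        report = _stage(
            "evaluate-predictions", lambda: prediction_eval.summarize_counts(counts)
        )
        outputs["prediction_report"] = out_dir / "prediction_report.tsv"
        io.write_table(report, outputs["prediction_report"])

    if utrs_path is not None and mirnas_path is not None and track_path is not None:
        utrs = _stage("read-utrs", lambda: io.read_fasta(utrs_path))
        mirnas = _stage("read-mirnas", lambda: io.read_fasta(mirnas_path))
        tracks = _stage("read-track", lambda: io.read_conservation(track_path))
        window_table, profile, tests = _stage(
            "mre-profile",
            lambda: mre_profile(utrs, mirnas, tracks, hits, config, group_mode),
        )
        outputs["mre_windows"] = out_dir / "mre_windows.tsv"
        io.write_table(window_table, outputs["mre_windows"])
        outputs["mre_profile"] = out_dir / "mre_profile.tsv"
        io.write_table(profile, outputs["mre_profile"])
        outputs["mre_tests"] = out_dir / "mre_tests.tsv"
        io.write_table(
            pd.DataFrame(
                {"comparison": list(tests), "p_value": list(tests.values())}
            ),
            outputs["mre_tests"],
        )

    manifest_path = out_dir / "manifest.json"
    io.write_manifest(outputs, config, manifest_path)
    outputs["manifest"] = manifest_path
    return outputs
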