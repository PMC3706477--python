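"""Synthetic dual-luciferase screens, UTR sequences and conservation tracks.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised end to end without wet-lab data:

* ``gen_screen`` — 96-well plates with per-plate empty-vector control
  wells, triplicate test wells per (miRNA, reporter) interaction, a
  multiplicative repression effect on the Renilla channel for true hits,
  and independent lognormal measurement noise on both luciferase channels
  (reporter RLUs are positive and right-skewed).
* ``gen_sequences`` — random 3'UTRs, half of which carry exact
  seed-complementary sites for a miRNA at recorded coordinates.
* ``gen_conservation_track`` — per-base scores in [0, 1] with a noisy
  baseline and a two-peak elevation over true sites (seed-target positions
  2-8 and miRNA-3'-end-target positions 14-25, site-relative).

All randomness flows from a single ``numpy`` generator seeded by the
config; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mre_conservation as mre
from .errors import ConfigError, InputError
from .screen_core import CONTROL_MIRNA_ID, ROLE_CONTROL, ROLE_TEST, WELL_COLUMNS

FIREFLY_BASELINE = 10_000.0  # RLU scale of the transfection-control channel
RENILLA_BASELINE = 5_000.0  # RLU scale of the reporter channel at no repression

#: site-relative label ranges elevated over true sites (two-peak pattern)
DEFAULT_PEAKS = ((2, 8), (14, 25))


@dataclass(frozen=True)
class ScreenSimConfig:
    """Parameters of a simulated reporter screen."""

    n_mirnas: int = 50
    n_reporters: int = 1
    hit_fraction: float = 0.1
    effect_fold: float = 0.5  # Renilla repression factor of true hits
    noise_cv: float = 0.1  # CV of the lognormal multiplicative noise
    replicates_per_interaction: int = 3
    controls_per_plate: int = 6
    wells_per_plate: int = 96
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_mirnas < 1 or self.n_reporters < 1:
            raise ConfigError("need at least one miRNA and one reporter")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ConfigError(f"hit_fraction {self.hit_fraction} outside [0, 1]")
        if not 0.0 < self.effect_fold <= 1.0:
            raise ConfigError(f"effect_fold {self.effect_fold} outside (0, 1]")
        if self.noise_cv < 0.0:
            raise ConfigError(f"noise_cv {self.noise_cv} must be >= 0")
        if self.replicates_per_interaction < 1:
            raise ConfigError("replicates_per_interaction must be >= 1")
        if self.controls_per_plate < 2:
            raise ConfigError("controls_per_plate must be >= 2")
        capacity = self.wells_per_plate - self.controls_per_plate
        if capacity < self.replicates_per_interaction:
            raise ConfigError("plate too small for controls plus one interaction")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth effect for one simulated interaction."""

    mirna_id: str
    reporter_id: str
    true_effect: float
    is_hit: bool = field(default=False)

    def __post_init__(self):
        object.__setattr__(self, "is_hit", self.true_effect < 1.0)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def _well_ids(n: int) -> list[str]:
    """Row-letter/column ids (A01..H12 for a 96-well plate)."""
    ids = []
    for i in range(n):
        row, col = divmod(i, 12)
        ids.append(f"{chr(ord('A') + row)}{col + 1:02d}")
    return ids


def gen_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a plate-based screen.

    Interactions (all miRNA x reporter pairs, reporter-major order) are
    filled plate by plate; an interaction's replicates share a plate, and
    every plate leads with its own control wells. Exactly
    ``round(hit_fraction * n_interactions)`` interactions are true hits
    with Renilla signal multiplied by ``effect_fold``.

    Returns
    -------
    (wells, truth): the well table in the canonical schema and the
    ground-truth table (mirna_id, reporter_id, true_effect, is_hit).
    """
    rng = np.random.default_rng(config.rng_seed)
    mirna_ids = [f"mir-{i + 1:04d}" for i in range(config.n_mirnas)]
    reporter_ids = [f"utr-{j + 1:03d}" for j in range(config.n_reporters)]
    interactions = [(m, r) for r in reporter_ids for m in mirna_ids]
    n_int = len(interactions)

    n_hits = round(config.hit_fraction * n_int)
    hit_idx = set(rng.choice(n_int, size=n_hits, replace=False).tolist())
    truths = [
        SyntheticTruth(m, r, config.effect_fold if i in hit_idx else 1.0)
        for i, (m, r) in enumerate(interactions)
    ]

    per_plate = (
        config.wells_per_plate - config.controls_per_plate
    ) // config.replicates_per_interaction
    rows = []
    for plate_no, chunk_start in enumerate(range(0, n_int, per_plate), start=1):
        chunk = truths[chunk_start : chunk_start + per_plate]
        plate_id = f"plate-{plate_no:03d}"
        n_wells = config.controls_per_plate + len(chunk) * config.replicates_per_interaction
        well_ids = _well_ids(n_wells)
        firefly = FIREFLY_BASELINE * _lognormal_factors(rng, config.noise_cv, n_wells)
        renilla_noise = _lognormal_factors(rng, config.noise_cv, n_wells)
        plate_reporter = chunk[0].reporter_id
        w = 0
        for rep in range(1, config.controls_per_plate + 1):
            rows.append(
                (
                    plate_id,
                    well_ids[w],
                    ROLE_CONTROL,
                    CONTROL_MIRNA_ID,
                    plate_reporter,
                    rep,
                    firefly[w],
                    RENILLA_BASELINE * renilla_noise[w],
                )
            )
            w += 1
        for truth in chunk:
            for rep in range(1, config.replicates_per_interaction + 1):
                rows.append(
                    (
                        plate_id,
                        well_ids[w],
                        ROLE_TEST,
                        truth.mirna_id,
                        truth.reporter_id,
                        rep,
                        firefly[w],
                        RENILLA_BASELINE * truth.true_effect * renilla_noise[w],
                    )
                )
                w += 1

    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    truth_df = pd.DataFrame(
        {
            "mirna_id": [t.mirna_id for t in truths],
            "reporter_id": [t.reporter_id for t in truths],
            "true_effect": [t.true_effect for t in truths],
            "is_hit": [t.is_hit for t in truths],
        }
    )
    return wells, truth_df


def gen_sequences(
    n_utrs: int,
    utr_length: int,
    mirnas: list[str],
    sites_per_positive: int = 1,
    rng_seed: int = 0,
    flank5: int = mre.FLANK5_DEFAULT,
    flank3: int = mre.FLANK3_DEFAULT,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Random 3'UTRs with seed-complementary sites embedded in half of them.

    Every odd-indexed UTR is a "positive" carrying ``sites_per_positive``
    exact seed-complement sites (reverse complement of miRNA positions 1-8)
    for one miRNA, cycled from ``mirnas``. Sites are placed non-overlapping
    and at least one flank away from the UTR ends so the standard MRE
    window always fits. Coordinates in the truth table are 0-based
    half-open on the UTR sense strand.

    Returns
    -------
    (mirna map, utr map, site truth table with columns
    utr_id, mirna_id, site_start, site_end). Sequences are stored as DNA
    (U mapped to T).
    """
    if not mirnas:
        raise InputError("need at least one miRNA sequence")
    motifs = [mre.seed_complement(m) for m in mirnas]  # validates length >= 8
    site_len = len(motifs[0])
    min_len = flank5 + site_len + flank3
    if utr_length < min_len:
        raise InputError(f"utr_length {utr_length} < window length {min_len}")

    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    mirna_map = {
        f"mir-{i + 1:03d}": mre._to_dna(seq) for i, seq in enumerate(mirnas)
    }
    mirna_ids = list(mirna_map)

    utr_map: dict[str, str] = {}
    records = []
    for u in range(n_utrs):
        utr_id = f"utr-{u + 1:03d}"
        seq = rng.choice(bases, size=utr_length)
        if u % 2 == 0 and sites_per_positive > 0:
            mid = mirna_ids[(u // 2) % len(mirna_ids)]
            motif = motifs[mirna_ids.index(mid)]
            placed: list[int] = []
            lo, hi = flank5, utr_length - site_len - flank3
            attempts = 0
            while len(placed) < sites_per_positive:
                attempts += 1
                if attempts > 1000:
                    raise ConfigError(
                        "could not place non-overlapping sites; UTR too short"
                    )
                start = int(rng.integers(lo, hi + 1))
                if all(abs(start - p) >= site_len for p in placed):
                    placed.append(start)
            for start in sorted(placed):
                seq[start : start + site_len] = list(motif)
                records.append((utr_id, mid, start, start + site_len))
        utr_map[utr_id] = "".join(seq)
    truth = pd.DataFrame(
        records, columns=["utr_id", "mirna_id", "site_start", "site_end"]
    )
    return mirna_map, utr_map, truth


def gen_conservation_track(
    utrs: dict[str, str],
    site_table: pd.DataFrame,
    base_level: float = 0.1,
    site_boost: float = 0.5,
    rng_seed: int = 0,
    noise_sd: float = 0.02,
    peaks: tuple[tuple[int, int], ...] = DEFAULT_PEAKS,
) -> dict[str, np.ndarray]:
    """Per-base conservation scores with two-peak elevation at true sites.

    Scores are ``base_level`` plus Gaussian jitter (sd ``noise_sd``),
    clipped to [0, 1]. Positions whose site-relative label (site start = 1)
    falls in one of the ``peaks`` ranges of a true site get ``site_boost``
    added before clipping, so the expected score there is
    base_level + site_boost.
    """
    if base_level < 0.0 or base_level + site_boost > 1.0 or site_boost < 0.0:
        raise ConfigError(
            f"base_level {base_level} + site_boost {site_boost} outside [0, 1]"
        )
    rng = np.random.default_rng(rng_seed)
    tracks: dict[str, np.ndarray] = {}
    for utr_id, seq in utrs.items():
        tracks[utr_id] = base_level + rng.normal(0.0, noise_sd, size=len(seq))
    for row in site_table.itertuples(index=False):
        track = tracks[row.utr_id]
        for lo, hi in peaks:
            # label L maps to UTR position site_start + L - 1
            start = row.site_start + lo - 1
            end = row.site_start + hi  # half-open
            start = max(start, 0)
            end = min(end, len(track))
            if start < end:
                track[start:end] += site_boost
    return {k: np.clip(v, 0.0, 1.0) for k, v in tracks.items()}
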