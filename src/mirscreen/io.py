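"""Readers and writers for the pipeline's file formats, plus run configuration.

Canonical on-disk formats are diffable text: TSV with a header row (UTF-8,
'.' decimal) for tables, FASTA for sequences, fixed-step wiggle (step 1)
for per-base conservation tracks. FASTA goes through Biopython; the wig
text dialect has a small hand-written reader/writer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, ParseError
from .screen_core import ROLE_CONTROL, ROLE_TEST, WELL_COLUMNS

_DNA = set("ACGT")


@dataclass(frozen=True)
class RunConfig:
    """Tunable analysis parameters shared across pipeline stages."""

    alpha: float = 0.05
    ssmd_strong: float = -2.0
    ssmd_extreme: float = -3.0
    seed_mode: str = "m1_8"  # m1_8: 8-nt site (miRNA 1-8); m2_8: 7-nt (2-8)
    flank5: int = 10
    flank3: int = 24
    rng_seed: int = 0
    rounding: int = 1

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.ssmd_extreme > self.ssmd_strong:
            raise ConfigError("ssmd_extreme must be <= ssmd_strong")
        if self.seed_mode not in ("m1_8", "m2_8"):
            raise ConfigError(f"unknown seed_mode {self.seed_mode!r}")
        if self.flank5 < 0 or self.flank3 < 0:
            raise ConfigError("flanks must be non-negative")

    @property
    def seed_span(self) -> tuple[int, int]:
        return (1, 8) if self.seed_mode == "m1_8" else (2, 8)


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON, a YAML subset) mapping."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(f"config file {path} is not a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------- plate TSV


def read_plate_table(path) -> pd.DataFrame:
    """Read a well table, validating schema, roles and uniqueness."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well_id": str})
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot read plate table {path}: {exc}") from exc
    missing = set(WELL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"plate table missing column(s): {sorted(missing)}")
    bad_roles = set(df["role"]) - {ROLE_TEST, ROLE_CONTROL}
    if bad_roles:
        raise ParseError(f"invalid role value(s): {sorted(bad_roles)}")
    for col in ("firefly_rlu", "renilla_rlu"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise ParseError(f"non-numeric {col} at row {row}")
        df[col] = vals
    dup = df.duplicated(subset=["plate_id", "well_id"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["plate_id", "well_id"]].tolist()
        raise ParseError(f"duplicate well {key[1]!r} on plate {key[0]!r}")
    return df[WELL_COLUMNS]


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot read table {path}: {exc}") from exc


# -------------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, str]:
    """FASTA -> id-to-sequence map, uppercase DNA with U mapped to T."""
    records: dict[str, str] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, OSError) as exc:
        raise ParseError(f"cannot read FASTA {path}: {exc}") from exc
    if not parsed:
        raise ParseError(f"FASTA {path} contains no records")
    for rec in parsed:
        if rec.id in records:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _DNA
        if bad:
            raise ParseError(
                f"illegal character(s) {sorted(bad)} in FASTA record {rec.id!r}"
            )
        records[rec.id] = seq
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ----------------------------------------------------------- fixed-step wig


def write_wiggle(tracks: dict[str, np.ndarray], path) -> None:
    """Write per-base tracks as fixed-step wiggle (start=1, step=1)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, values in tracks.items():
            fh.write(f"fixedStep chrom={name} start=1 step=1\n")
            for v in np.asarray(values, dtype=float):
                fh.write(f"{v:.6g}\n")


def read_wiggle(path) -> dict[str, np.ndarray]:
    """Parse fixed-step wiggle text (step 1 only) into per-base tracks."""
    tracks: dict[str, list[float]] = {}
    current: list[float] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    item.split("=", 1) for item in line.split()[1:] if "=" in item
                )
                if "chrom" not in fields:
                    raise ParseError(f"{path}:{lineno}: fixedStep without chrom")
                if int(fields.get("step", 1)) != 1 or int(fields.get("start", 1)) != 1:
                    raise ParseError(
                        f"{path}:{lineno}: only start=1 step=1 tracks are supported"
                    )
                name = fields["chrom"]
                if name in tracks:
                    raise ParseError(f"{path}:{lineno}: duplicate track {name!r}")
                current = tracks.setdefault(name, [])
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: data before fixedStep header")
                try:
                    current.append(float(line))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score {line!r}") from exc
    if not tracks:
        raise ParseError(f"wiggle {path} contains no tracks")
    return {k: np.asarray(v) for k, v in tracks.items()}


def read_conservation(path) -> dict[str, np.ndarray]:
    """Read a conservation track from wiggle or per-base TSV.

    The TSV alternative has columns seq_id, pos (0-based), score and must
    cover 0..len-1 contiguously per sequence.
    """
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    if head.startswith(("fixedStep", "track")):
        return read_wiggle(path)
    df = read_table(path)
    missing = {"seq_id", "pos", "score"} - set(df.columns)
    if missing:
        raise ParseError(f"conservation TSV missing column(s): {sorted(missing)}")
    tracks = {}
    for seq_id, group in df.groupby("seq_id", sort=False):
        group = group.sort_values("pos")
        if not (group["pos"].to_numpy() == np.arange(len(group))).all():
            raise ParseError(f"conservation positions for {seq_id!r} not contiguous")
        tracks[seq_id] = group["score"].to_numpy(dtype=float)
    return tracks


# ----------------------------------------------------------------- manifest


def write_manifest(outputs: dict[str, Path], config, path) -> None:
    """Record every written file with a checksum plus the exact config."""
    import hashlib

    entries = {}
    for name, p in outputs.items():
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        entries[name] = {"path": str(p), "sha256": digest}
    payload = {
        "config": dataclasses.asdict(config) if dataclasses.is_dataclass(config) else config,
        "outputs": entries,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
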