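"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are 0-based half-open internally; breakends are single
0-based positions. BEDPE/BED are native; any 1-based inputs must be converted
at the boundary by the caller. Sample joining across matrices is strict exact
string match. Reader followed by writer is the identity on valid files
(floats are written with the fixed ``%.6g`` format).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SV_CLASSES = {"DEL", "DUP", "INV", "INS", "TRA", "UNKNOWN"}
#: tokens treated as missing in TSV matrices (configurable per call)
DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan")

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A malformed input file; the message names the offending line/column."""


@dataclass(frozen=True)
class SVCall:
    """One somatic structural variant: a pair of oriented breakends."""

    sample_id: str
    chrom1: str
    pos1: int
    orient1: str
    chrom2: str
    pos2: int
    orient2: str
    sv_class: str = "UNKNOWN"
    source: str = "."
    sv_id: str = "."

    def __post_init__(self):
        if self.pos1 < 0 or self.pos2 < 0:
            raise FormatError(f"negative breakend position in SV {self.sv_id}")
        if self.orient1 not in "+-" or self.orient2 not in "+-":
            raise FormatError(f"bad orientation in SV {self.sv_id}")


@dataclass(frozen=True)
class GeneModel:
    """Gene interval, 0-based half-open, with strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def anchor(self) -> int:
        """Transcription start: ``start`` on +, ``end`` on - strand."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    cancer_type: str
    batch: str = "batch0"
    os_months: float | None = None
    os_event: int | None = None

    def __post_init__(self):
        if (self.os_months is None) != (self.os_event is None):
            raise FormatError(
                f"sample {self.sample_id}: os_months and os_event must be "
                "jointly present or jointly missing"
            )


@dataclass
class RunConfig:
    """Thresholds and windows for the whole pipeline (defaults as published)."""

    # region windows, bp
    upstream_window: int = 100_000
    downstream_window: int = 100_000
    flank_window: int = 1_000_000
    # association scan
    oe_sd: float = 0.4
    fdr_cut: float = 0.10
    min_bp_tumors: int = 3
    min_obs: int = 400
    meth_delta: float = 0.2
    # mechanism detectors
    enh_scan: int = 500_000
    enh_ref: int = 1_000_000
    retro_scan: int = 20_000
    low_meth: float = -0.1
    # cell-line dependencies
    effect_cut: float = -0.5
    min_lines: int = 7
    min_line_frac: float = 0.05
    # fusion cross-sample evidence
    cross_sample_frac: float = 0.20
    # survival
    survival_cap_months: float = 200.0
    covariate_mode: str = "cancer_type"  # or "batch"
    seed: int = 0

    def __post_init__(self):
        for name in (
            "upstream_window", "downstream_window", "flank_window", "oe_sd",
            "fdr_cut", "min_bp_tumors", "min_obs", "meth_delta", "enh_scan",
            "enh_ref", "retro_scan", "min_lines", "min_line_frac",
            "cross_sample_frac", "survival_cap_months",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")
        if self.covariate_mode not in ("cancer_type", "batch"):
            raise ValueError("covariate_mode must be 'cancer_type' or 'batch'")

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class Matrix:
    """Feature x sample real matrix with an explicit missingness mask.

    ``values`` holds NaN where missing; ``mask`` is True where observed.
    """

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature IDs: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")

    @property
    def mask(self) -> pd.DataFrame:
        return self.values.notna()

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def n_observed(self) -> pd.Series:
        return self.mask.sum(axis=1)


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "sample_id", "sv_class",
]


def read_sv_bedpe(path) -> list[SVCall]:
    """Read somatic SV calls from BEDPE (>=10 standard columns + sample/class).

    Breakend positions are ``start1``/``start2``, interpreted 0-based.
    Malformed rows raise :class:`FormatError` naming the line number; an
    unrecognized sv_class becomes UNKNOWN.
    """
    calls: list[SVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=10 BEDPE columns "
                    f"(missing strand1/strand2?), got {len(parts)}"
                )
            (chrom1, start1, _end1, chrom2, start2, _end2,
             name, _score, strand1, strand2) = parts[:10]
            sample_id = parts[10] if len(parts) > 10 else "."
            sv_class = parts[11] if len(parts) > 11 else "UNKNOWN"
            if sv_class not in SV_CLASSES:
                if sv_class in ("AMP", "DUP/AMP"):
                    sv_class = "DUP"
                else:
                    sv_class = "UNKNOWN"
            try:
                pos1, pos2 = int(start1), int(start2)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer position"
                ) from exc
            if pos1 < 0 or pos2 < 0:
                raise FormatError(
                    f"{path}: line {lineno}: negative breakend position"
                )
            if strand1 not in "+-" or strand2 not in "+-":
                raise FormatError(
                    f"{path}: line {lineno}: strand1/strand2 must be + or -"
                )
            calls.append(SVCall(
                sample_id=sample_id, chrom1=chrom1, pos1=pos1, orient1=strand1,
                chrom2=chrom2, pos2=pos2, orient2=strand2, sv_class=sv_class,
                source=".", sv_id=name,
            ))
    return calls


def write_sv_bedpe(calls: Iterable[SVCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write("\t".join([
                c.chrom1, str(c.pos1), str(c.pos1 + 1),
                c.chrom2, str(c.pos2), str(c.pos2 + 1),
                c.sv_id, "0", c.orient1, c.orient2, c.sample_id, c.sv_class,
            ]) + "\n")


# ---------------------------------------------------------------------------
# BED (genes, enhancers, repeats, TADs)
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, gene_id, score, strand)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected BED6")
            chrom, start, end, gene_id, _score, strand = parts[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start >= end (coordinate sense)"
                )
            if gene_id in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate gene_id "
                                  f"{gene_id}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


def write_gene_bed(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                     f"{g.strand}\n")


def read_bed_intervals(path) -> pd.DataFrame:
    """Read a plain BED (>=3 cols) into a DataFrame (chrom, start, end, name)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected BED3+")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed_intervals(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\n")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------

def read_matrix_tsv(path, na_tokens: Sequence[str] = DEFAULT_NA_TOKENS) -> Matrix:
    """Read a feature x sample TSV matrix.

    First column is feature IDs, header row is sample IDs, configurable NA
    tokens are treated as missing. Ragged rows, duplicate sample IDs and
    duplicate feature IDs are errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise FormatError(f"{path}: duplicate sample IDs in header")
        feats: list[str] = []
        data: list[list[float]] = []
        na = set(na_tokens)
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: ragged row ({len(parts)} fields, "
                    f"expected {len(header)})"
                )
            feats.append(parts[0])
            row = []
            for j, tok in enumerate(parts[1:], 1):
                if tok in na:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(tok))
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: line {lineno}: non-numeric cell "
                            f"{tok!r} (not an NA token)"
                        ) from exc
            data.append(row)
    if len(set(feats)) != len(feats):
        raise FormatError(f"{path}: duplicate feature IDs")
    values = pd.DataFrame(data, index=pd.Index(feats, name=header[0]),
                          columns=samples, dtype=float)
    return Matrix(values)


def write_matrix_tsv(matrix: Matrix | pd.DataFrame, path,
                     index_name: str = "feature") -> None:
    values = matrix.values if isinstance(matrix, Matrix) else matrix
    with open(path, "w") as fh:
        name = values.index.name or index_name
        fh.write("\t".join([name, *map(str, values.columns)]) + "\n")
        arr = values.to_numpy()
        for i, feat in enumerate(values.index):
            cells = [
                "" if np.isnan(v) else FLOAT_FMT % v for v in arr[i]
            ]
            fh.write("\t".join([str(feat), *cells]) + "\n")


# ---------------------------------------------------------------------------
# Simple record tables
# ---------------------------------------------------------------------------

def read_samples_tsv(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        months = getattr(row, "os_months", None)
        event = getattr(row, "os_event", None)
        months = None if months in (None, "") or pd.isna(months) else float(months)
        event = None if event in (None, "") or pd.isna(event) else int(event)
        records.append(SampleRecord(
            sample_id=row.sample_id, patient_id=row.patient_id,
            cancer_type=row.cancer_type,
            batch=getattr(row, "batch", "batch0"),
            os_months=months, os_event=event,
        ))
    return records


def write_samples_tsv(records: Iterable[SampleRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpatient_id\tcancer_type\tbatch\tos_months\t"
                 "os_event\n")
        for r in records:
            months = "" if r.os_months is None else FLOAT_FMT % r.os_months
            event = "" if r.os_event is None else str(r.os_event)
            fh.write(f"{r.sample_id}\t{r.patient_id}\t{r.cancer_type}\t"
                     f"{r.batch}\t{months}\t{event}\n")


def read_table_tsv(path) -> pd.DataFrame:
    """Generic TSV table (MAF-lite, fusion candidates, probe annotation...)."""
    return pd.read_csv(path, sep="\t", dtype={0: str}, keep_default_na=False,
                       na_values=[""])


def write_table_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def align_samples(*objects, sample_lists: Sequence[Sequence[str]]):
    """Strict intersection of sample-ID lists (exact string match).

    Returns the ordered common list (order of the first list) and the number
    dropped from each input; unmatched samples are dropped, never imputed.
    """
    common = set(sample_lists[0])
    for lst in sample_lists[1:]:
        common &= set(lst)
    ordered = [s for s in sample_lists[0] if s in common]
    dropped = [len(lst) - len(common) for lst in sample_lists]
    return ordered, dropped


def write_manifest(path, config: RunConfig, inputs: dict, seed: int) -> None:
    """JSON run manifest: inputs, config hash, seed (no timestamps, so two
    identical runs produce byte-identical manifests)."""
    import svcis
    payload = {
        "inputs": {k: str(v) for k, v in sorted(inputs.items())},
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": seed,
        "package": "svcis",
        "version": svcis.__version__,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
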