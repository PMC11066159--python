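"""Fluorescence-screen quantification of codon reassignment efficiency.

The screen brackets each sample between two reference constructs measured
under the same conditions: a 100% reference (the reporter codon encodes the
amino acid required for fluorophore formation) and a 0% reference (it
encodes another amino acid, so only residual cell/media fluorescence is
seen).  A sample's reassignment efficiency (RE) is its mean per-cell
fluorescence mapped affinely onto that bracket:

    RE = 100 * (sample - ref0) / (ref100 - ref0)   [percent]

Replicates are aggregated as mean +/- sample standard deviation (n-1
denominator).  Efficiencies below the screen's limit of detection (LOD,
0.2% by default, set by residual fluorescence of cells and growth media)
are flagged as censored; the raw mean is preserved for audit but must not
enter ratio arithmetic directly (see ``discrimination_stats``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .discrimination_stats import DEFAULT_LOD
from .errors import DegenerateReferenceError, DomainError

#: Construct labels used in screen tables.
SAMPLE, REF0, REF100 = "sample", "ref0", "ref100"

SCREEN_COLUMNS = ["replicate_id", "construct", "anticodon", "codon", "value"]


@dataclass(frozen=True)
class RawMeasurement:
    """One plate-reader measurement: mean per-cell fluorescence (a.u.)."""

    value: float
    replicate_id: str = ""
    construct: str = SAMPLE

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise DomainError(
                f"fluorescence must be finite and >= 0, got {self.value}"
            )


@dataclass(frozen=True)
class ReassignmentEfficiency:
    """Aggregated reassignment efficiency: mean +/- sd percent over n
    replicates, with LOD censoring status."""

    mean: float
    sd: float
    n: int
    below_lod: bool = False
    lod: float = DEFAULT_LOD

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError(f"sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")


def _value(x) -> float:
    return x.value if isinstance(x, RawMeasurement) else float(x)


def normalize_measurement(sample, ref0, ref100) -> float:
    """Map a raw fluorescence value onto the 0-100% reference bracket.

    Accepts :class:`RawMeasurement` objects or bare numbers.  The result is
    not clipped: noisy samples may fall slightly outside [0, 100].
    """
    s, lo, hi = _value(sample), _value(ref0), _value(ref100)
    if hi <= lo:
        raise DegenerateReferenceError(
            f"ref100 ({hi}) must exceed ref0 ({lo})"
        )
    return 100.0 * (s - lo) / (hi - lo)


def aggregate_replicates(values: Sequence[float]) -> ReassignmentEfficiency:
    """Mean and sample standard deviation (sd = 0 when n = 1) of
    per-replicate efficiencies (percent)."""
    values = list(values)
    n = len(values)
    if n == 0:
        raise DomainError("cannot aggregate an empty replicate list")
    mean = sum(values) / n
    if n == 1:
        sd = 0.0
    else:
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return ReassignmentEfficiency(mean=mean, sd=sd, n=n)


def apply_lod(
    re: ReassignmentEfficiency, lod: float = DEFAULT_LOD
) -> ReassignmentEfficiency:
    """Flag an efficiency below the limit of detection.

    The comparison is strict: a mean exactly at the LOD counts as detected.
    The mean itself is preserved for audit.
    """
    if lod <= 0:
        raise DomainError(f"lod must be positive, got {lod}")
    return replace(re, below_lod=bool(re.mean < lod), lod=lod)


def read_screen_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV screen table (delimiter sniffed from the extension).

    Required columns: replicate_id, construct, anticodon, codon, value.
    An optional ``batch`` column pairs samples with their own reference
    wells; without it all rows form a single batch.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"replicate_id": str})
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"screen table missing columns: {missing}")
    return df


def analyze_screen_table(
    df: pd.DataFrame,
    lod: float = DEFAULT_LOD,
    batch_col: str | None = None,
) -> pd.DataFrame:
    """Normalize, aggregate and censor a full screen table.

    References are paired per batch (``batch_col``, or a ``batch`` column if
    present, else one global batch); each batch's ref0/ref100 level is the
    mean of its reference wells.  Returns one row per (anticodon, codon)
    with columns mean, sd, n, below_lod.
    """
    if batch_col is None and "batch" in df.columns:
        batch_col = "batch"
    if batch_col is None:
        df = df.assign(_batch="all")
        batch_col = "_batch"

    records = []
    for batch, sub in df.groupby(batch_col, sort=False):
        ref0_rows = sub.loc[sub["construct"] == REF0, "value"]
        ref100_rows = sub.loc[sub["construct"] == REF100, "value"]
        if ref0_rows.empty or ref100_rows.empty:
            raise DomainError(f"batch {batch!r} is missing reference wells")
        ref0 = float(ref0_rows.mean())
        ref100 = float(ref100_rows.mean())
        samples = sub[sub["construct"] == SAMPLE]
        for (anticodon, codon), grp in samples.groupby(
            ["anticodon", "codon"], sort=False
        ):
            normalized = [
                normalize_measurement(v, ref0, ref100) for v in grp["value"]
            ]
            re = apply_lod(aggregate_replicates(normalized), lod=lod)
            records.append(
                {
                    "anticodon": anticodon,
                    "codon": codon,
                    "mean": re.mean,
                    "sd": re.sd,
                    "n": re.n,
                    "below_lod": re.below_lod,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["anticodon", "codon", "mean", "sd", "n", "below_lod"]
    )


def write_re_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an aggregated RE table as TSV."""
    pd.DataFrame(df).to_csv(path, sep="\t", index=False)


def efficiencies_from_table(
    df: pd.DataFrame,
) -> dict[tuple[str, str], ReassignmentEfficiency]:
    """Convert an aggregated RE table into keyed
    :class:`ReassignmentEfficiency` records."""
    out = {}
    for row in df.itertuples(index=False):
        out[(row.anticodon, row.codon)] = ReassignmentEfficiency(
            mean=float(row.mean),
            sd=float(row.sd),
            n=int(row.n),
            below_lod=bool(row.below_lod),
        )
    return out
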