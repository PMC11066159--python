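"""U3:C3 discrimination ratios and the inosine-detectability model.

The discrimination ratio summarises how a single tRNA species splits its
decoding events between the U-ending and C-ending codons of its box,
independent of the tRNA's absolute activity:

    raw_fraction = RE_U / (RE_U + RE_C)

where RE_U and RE_C are the reassignment efficiencies (percent) at the U-
and C-ending codons.  The ratio is reported as integer shares of 100
("number of times out of 100 incorporation events"), e.g. ``55:45``.  When
the C-ending codon is below the screen's limit of detection (LOD), the true
ratio is unknown but bounded from below; the censored floor substitutes the
LOD for RE_C and is displayed with a ``>=`` prefix, e.g. ``>=95:5``.

The detectability model answers "how much inosine modification would be
visible as anomalous C-ending decoding?".  Under linear mixing, a fraction
f_I of inosine-modified molecules decodes the C-ending codon at
RE_C = f_I * RE_U; modification is detectable once RE_C clears a small
multiple ``k`` of the LOD, giving a minimum detectable fraction of
k * LOD / RE_U (capped at 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

#: Limit of detection of the fluorescence screen, percent reassignment.
DEFAULT_LOD = 0.2


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class DiscriminationRatio:
    """Integer U:C shares of 100 decoding events for one tRNA.

    ``is_floor`` marks a censored lower bound (RE_C below the LOD, ratio
    computed against the LOD itself).  ``raw_fraction`` keeps the
    un-rounded U fraction for downstream arithmetic.
    """

    u_share: int
    c_share: int
    is_floor: bool
    raw_fraction: float

    def __post_init__(self) -> None:
        if self.u_share + self.c_share != 100:
            raise DomainError(
                f"shares must sum to 100, got {self.u_share}+{self.c_share}"
            )
        if not 0.0 <= self.raw_fraction <= 1.0:
            raise DomainError(f"raw_fraction outside [0,1]: {self.raw_fraction}")


@dataclass(frozen=True)
class DetectabilityModel:
    """Linear-mixing model for when inosine modification becomes visible.

    A fraction ``f_I`` of modified tRNA decodes the C-ending codon at
    ``RE_C = f_I * RE_U``; the screen flags this once ``RE_C >= k * lod``.
    ``k`` is a calibrated detection multiple (default 2, i.e. anomalous
    decoding must clear twice the LOD).
    """

    lod: float = DEFAULT_LOD
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise DomainError(f"lod must be positive, got {self.lod}")
        if self.k < 1:
            raise DomainError(f"detection multiple k must be >= 1, got {self.k}")


def discrimination_ratio(re_u: float, re_c: float) -> DiscriminationRatio:
    """Discrimination ratio from uncensored U- and C-ending efficiencies.

    Both arguments are percent reassignment.  Integer shares are produced by
    rounding the U share half-up; the C share is the complement.
    """
    if re_u <= 0:
        raise DomainError(f"re_u must be positive, got {re_u}")
    if re_c < 0:
        raise DomainError(f"re_c must be non-negative, got {re_c}")
    raw = re_u / (re_u + re_c)
    u = round_half_up(100.0 * raw)
    return DiscriminationRatio(u, 100 - u, is_floor=False, raw_fraction=raw)


def discrimination_floor(
    re_u: float, lod: float = DEFAULT_LOD
) -> DiscriminationRatio:
    """Lower-bound ratio when the C-ending codon is below the LOD.

    Substitutes the LOD for the unobservable RE_C, so the true ratio is at
    least this large.
    """
    if re_u <= 0:
        raise DomainError(f"re_u must be positive, got {re_u}")
    if lod <= 0:
        raise DomainError(f"lod must be positive, got {lod}")
    raw = re_u / (re_u + lod)
    u = round_half_up(100.0 * raw)
    return DiscriminationRatio(u, 100 - u, is_floor=True, raw_fraction=raw)


def format_ratio(dr: DiscriminationRatio) -> str:
    """Display form, e.g. ``"55:45"``; floors are prefixed ``">="`` rendered
    as the single character ≥."""
    prefix = "≥" if dr.is_floor else ""
    return f"{prefix}{dr.u_share}:{dr.c_share}"


def min_detectable_inosine_fraction(
    re_u: float, model: DetectabilityModel | None = None
) -> float:
    """Smallest inosine-modified fraction visible as anomalous C3 decoding.

    For a tRNA whose U-ending reassignment is ``re_u`` percent, returns
    ``min(1, k*lod/re_u)``: strong reassigners reveal small modified
    fractions (2% at RE_U = 20), weak ones need substantial modification
    (40% at RE_U = 1).
    """
    if model is None:
        model = DetectabilityModel()
    if re_u <= 0:
        raise DomainError(f"re_u must be positive, got {re_u}")
    return min(1.0, model.k * model.lod / re_u)
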