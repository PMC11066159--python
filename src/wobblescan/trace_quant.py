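"""Sanger-trace parsing and quantification of A-to-I editing at position 34.

Reverse transcriptase reads inosine as guanosine and incorporates C into the
cDNA, whereas unmodified adenosine templates only T.  Sequencing the strand
complementary to the tRNA therefore turns the modified fraction at anticodon
position 34 into a mixed T/C peak: the C share of the combined T+C signal at
that trace position estimates the inosine-modified fraction.

Because the sequenced strand is the reverse complement of the tRNA, the
anticodon appears in sequencing output as the DNA spelling of the targeted
codon, and position 34 is the *third* base of that triplet (antiparallel
reversal puts the 5'-most anticodon base last in reading order).

Supported trace containers: ABIF (.ab1, parsed with Biopython and mapped
through the FWO_ channel-order tag), a simple XML trace dialect, and a CSV
trace table.  Base calls and peak locations are taken as given; no
base-calling or mobility correction is performed.
"""

from __future__ import annotations

import io
import re
import struct
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    DomainError,
    LocalizationError,
    NoSignalError,
    TraceFormatError,
)

DNA_BASES = "ACGT"

#: Baseline percentile subtracted per channel before peak integration.
BASELINE_PERCENTILE = 5.0

#: Default visibility threshold for calling inosine modification (fraction).
DEFAULT_MODIFICATION_THRESHOLD = 0.05


@dataclass
class Chromatogram:
    """A four-channel electropherogram with peak calls.

    ``channels`` maps each DNA base to its analyzed signal array (all the
    same length); ``peak_locations`` gives one sample index per called base;
    ``channel_order`` records the on-disk channel permutation (the ABIF
    ``FWO_`` convention, default ``"GATC"``).
    """

    channels: dict[str, np.ndarray]
    peak_locations: np.ndarray
    called_bases: str
    channel_order: str = "GATC"

    def __post_init__(self) -> None:
        self.channels = {b: np.asarray(v) for b, v in self.channels.items()}
        self.peak_locations = np.asarray(self.peak_locations, dtype=int)
        self.validate()

    def validate(self) -> None:
        if sorted(self.channels) != sorted(DNA_BASES):
            raise TraceFormatError(
                f"channels must be keyed by {DNA_BASES}, got {sorted(self.channels)}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise TraceFormatError(f"unequal channel lengths: {lengths}")
        (n,) = lengths
        if n == 0:
            raise TraceFormatError("empty trace arrays")
        if sorted(self.channel_order) != sorted(DNA_BASES):
            raise TraceFormatError(
                f"channel_order must permute {DNA_BASES}, got {self.channel_order!r}"
            )
        if len(self.called_bases) != len(self.peak_locations):
            raise TraceFormatError(
                "called_bases and peak_locations differ in length"
            )
        if len(self.peak_locations):
            if np.any(np.diff(self.peak_locations) <= 0):
                raise TraceFormatError("peak_locations not strictly increasing")
            if self.peak_locations[0] < 0 or self.peak_locations[-1] >= n:
                raise TraceFormatError("peak_locations outside trace bounds")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass(frozen=True)
class TraceLocus:
    """Location of the sequenced anticodon triplet within a trace.

    ``anticodon_window`` holds the three consecutive called-base indices of
    the triplet in sequencing order; ``trace_index`` is the third of them,
    the base complementary to tRNA position 34.
    """

    anticodon_window: tuple[int, int, int]
    trace_index: int
    orientation: str = "reverse_complement"


@dataclass(frozen=True)
class PeakAreas:
    """Baseline-subtracted signal per channel at one peak.

    ``areas`` are trapezoidal integrals (or peak heights when measured with
    ``method="height"``), clamped at zero; ``window`` records the sample
    bounds used.
    """

    areas: dict[str, float] = field(hash=False)
    window: tuple[int, int] = (0, 0)

    def __getitem__(self, base: str) -> float:
        return self.areas[base]


@dataclass(frozen=True)
class InosineCall:
    """An inosine-modification call at position 34.

    ``fraction`` is the estimated modified fraction; ``modified`` requires
    both the absolute visibility threshold and a 3-sigma clearance over the
    trace's baseline C/(C+T) noise.
    """

    fraction: float
    baseline_noise_mean: float
    baseline_noise_sd: float
    modified: bool
    threshold: float = DEFAULT_MODIFICATION_THRESHOLD


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_ABIF_DATA_TAGS = ("DATA9", "DATA10", "DATA11", "DATA12")


def read_abif(source: bytes | str | Path) -> Chromatogram:
    """Parse an ABIF (.ab1) container into a :class:`Chromatogram`.

    Accepts raw bytes or a file path.  Analyzed channel data are taken from
    DATA9-12 and mapped to bases through the FWO_ channel order; peak
    locations from PLOC and called bases from PBAS (edited copy 2 preferred,
    copy 1 accepted).
    """
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
    else:
        data = bytes(source)
    if not data.startswith(b"ABIF"):
        raise TraceFormatError(
            f"not an ABIF file (magic {data[:4]!r}, expected b'ABIF')"
        )
    try:
        record = SeqIO.read(io.BytesIO(data), "abi")
    except (ValueError, struct.error, AssertionError) as exc:
        raise TraceFormatError(f"malformed ABIF container: {exc}") from exc
    raw = record.annotations.get("abif_raw", {})

    fwo = _require_tag(raw, ["FWO_1"])
    order = fwo.decode() if isinstance(fwo, bytes) else str(fwo)
    if sorted(order) != sorted(DNA_BASES):
        raise TraceFormatError(f"FWO_ is not a permutation of ACGT: {order!r}")

    channels = {}
    for i, tag in enumerate(_ABIF_DATA_TAGS):
        values = _require_tag(raw, [tag])
        channels[order[i]] = np.asarray(values, dtype=float)

    ploc = _require_tag(raw, ["PLOC2", "PLOC1"])
    pbas = _require_tag(raw, ["PBAS2", "PBAS1"])
    called = pbas.decode() if isinstance(pbas, bytes) else str(pbas)
    ploc_arr = np.atleast_1d(np.asarray(ploc, dtype=int))
    return Chromatogram(
        channels=channels,
        peak_locations=ploc_arr,
        called_bases=called,
        channel_order=order,
    )


def _require_tag(raw: dict, names: list[str]):
    for name in names:
        if name in raw and raw[name] is not None:
            return raw[name]
    raise TraceFormatError(f"ABIF container missing required tag {names[0]}")


def read_trace_xml(source: str | Path | io.IOBase) -> Chromatogram:
    """Parse the package's XML trace dialect.

    Expected document::

        <trace channel_order="GATC">
          <channel base="A">12 15 ...</channel>  (one per base)
          <peak_locations>6 18 ...</peak_locations>
          <called_bases>GAT...</called_bases>
        </trace>
    """
    try:
        if hasattr(source, "read"):
            root = ET.fromstring(source.read())
        elif isinstance(source, Path) or (
            isinstance(source, str) and "<" not in source
        ):
            root = ET.parse(source).getroot()
        else:
            root = ET.fromstring(source)
    except (ET.ParseError, OSError) as exc:
        raise TraceFormatError(f"malformed trace XML: {exc}") from exc

    channels = {}
    for elem in root.findall("channel"):
        base = elem.get("base")
        if base not in DNA_BASES:
            raise TraceFormatError(f"invalid channel base {base!r}")
        channels[base] = _parse_numbers(elem.text)
    missing = sorted(set(DNA_BASES) - set(channels))
    if missing:
        raise TraceFormatError(f"trace XML missing channels: {missing}")

    ploc_elem = root.find("peak_locations")
    bases_elem = root.find("called_bases")
    if ploc_elem is None or bases_elem is None:
        raise TraceFormatError(
            "trace XML missing peak_locations or called_bases element"
        )
    ploc = _parse_numbers(ploc_elem.text).astype(int)
    called = (bases_elem.text or "").strip()
    return Chromatogram(
        channels=channels,
        peak_locations=ploc,
        called_bases=called,
        channel_order=root.get("channel_order", "GATC"),
    )


def _parse_numbers(text: str | None) -> np.ndarray:
    if text is None or not text.strip():
        raise TraceFormatError("empty numeric array in trace document")
    return np.array([float(tok) for tok in text.split()])


def write_trace_xml(chrom: Chromatogram, path: str | Path | None = None) -> str:
    """Serialize a chromatogram to the XML trace dialect; returns the text
    and optionally writes it to ``path``."""
    root = ET.Element("trace", channel_order=chrom.channel_order)
    for base in DNA_BASES:
        elem = ET.SubElement(root, "channel", base=base)
        elem.text = " ".join(_fmt(v) for v in chrom.channels[base])
    ET.SubElement(root, "peak_locations").text = " ".join(
        str(int(p)) for p in chrom.peak_locations
    )
    ET.SubElement(root, "called_bases").text = chrom.called_bases
    text = ET.tostring(root, encoding="unicode")
    if path is not None:
        Path(path).write_text(text)
    return text


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def read_trace_csv(source: str | Path) -> Chromatogram:
    """Read a CSV trace table with columns index, A, C, G, T,
    peak_location, called_base (peak columns populated for the first
    n_peaks rows only)."""
    df = pd.read_csv(source)
    required = ["index", "A", "C", "G", "T"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceFormatError(f"trace CSV missing columns: {missing}")
    channels = {b: df[b].to_numpy(dtype=float) for b in DNA_BASES}
    if "peak_location" not in df.columns or "called_base" not in df.columns:
        raise TraceFormatError(
            "trace CSV missing peak_location/called_base columns"
        )
    peaks = df["peak_location"].dropna()
    calls = df["called_base"].dropna()
    return Chromatogram(
        channels=channels,
        peak_locations=peaks.to_numpy(dtype=int),
        called_bases="".join(calls.astype(str)),
    )


def write_trace_csv(chrom: Chromatogram, path: str | Path) -> None:
    """Write a chromatogram as a CSV trace table (see
    :func:`read_trace_csv`)."""
    n = chrom.n_samples
    df = pd.DataFrame({"index": np.arange(n)})
    for b in DNA_BASES:
        df[b] = chrom.channels[b]
    peak_col = pd.Series([pd.NA] * n, dtype="object")
    base_col = pd.Series([pd.NA] * n, dtype="object")
    k = len(chrom.peak_locations)
    peak_col.iloc[:k] = [int(p) for p in chrom.peak_locations]
    base_col.iloc[:k] = list(chrom.called_bases)
    df["peak_location"] = peak_col
    df["called_base"] = base_col
    df.to_csv(path, index=False)


def read_trace(path: str | Path) -> Chromatogram:
    """Dispatch on file extension: .ab1/.abi -> ABIF, .xml, .csv."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".ab1", ".abi", ".abif"):
        return read_abif(path)
    if suffix == ".xml":
        return read_trace_xml(path)
    if suffix == ".csv":
        return read_trace_csv(path)
    raise TraceFormatError(f"unrecognized trace extension {suffix!r}")


# ---------------------------------------------------------------------------
# Localization
# ---------------------------------------------------------------------------


def _split_marked_reference(reference_cdna: str) -> tuple[str, str, str]:
    """Split a reference cDNA into (left flank, triplet, right flank).

    The sequenced anticodon triplet is marked by lower-casing exactly those
    three bases in an otherwise upper-case reference.
    """
    runs = [(m.start(), m.group()) for m in re.finditer("[acgt]+", reference_cdna)]
    if len(runs) != 1 or len(runs[0][1]) != 3:
        raise LocalizationError(
            "reference cDNA must mark exactly one lowercase triplet "
            f"(found {[r[1] for r in runs]})"
        )
    start, triplet = runs[0]
    return reference_cdna[:start], triplet.upper(), reference_cdna[start + 3 :]


def locate_anticodon(
    chrom: Chromatogram,
    reference_cdna: str,
    flank: int = 12,
    max_edit_distance: int = 5,
) -> TraceLocus:
    """Find the trace position of the base complementary to tRNA base 34.

    The reference cDNA (sequenced-strand orientation, lowercase anticodon
    triplet) supplies ``flank`` bases of context on each side of the
    triplet.  The context is searched in the called bases with the triplet
    itself wildcarded (its third base is the very position whose identity is
    in question).  An exact match is tried first; failing that, a banded
    edit-distance alignment (unit costs) recovers the locus through a few
    miscalled flank bases, up to ``max_edit_distance`` edits.
    """
    left, triplet, right = _split_marked_reference(reference_cdna.strip())
    if len(left) < flank or len(right) < flank:
        raise LocalizationError(
            f"reference provides <{flank} bases of flanking context"
        )
    left_ctx = left[-flank:].upper()
    right_ctx = right[:flank].upper()
    called = chrom.called_bases.upper()

    pattern = re.escape(left_ctx) + "[ACGTN]{3}" + re.escape(right_ctx)
    matches = [m.start() for m in re.finditer(pattern, called)]
    if len(matches) > 1:
        raise LocalizationError(
            f"anticodon context found {len(matches)} times in called bases"
        )
    if len(matches) == 1:
        start = matches[0] + flank
    else:
        query = left_ctx + "NNN" + right_ctx
        result = edlib.align(
            query,
            called,
            mode="HW",
            task="locations",
            additionalEqualities=[("N", b) for b in DNA_BASES],
        )
        dist = result["editDistance"]
        if dist < 0 or dist > max_edit_distance:
            raise LocalizationError(
                f"anticodon context not found (best edit distance {dist}, "
                f"cap {max_edit_distance})"
            )
        loc_start = result["locations"][0][0]
        start = loc_start + flank
    window = (start, start + 1, start + 2)
    if window[2] >= len(chrom.peak_locations):
        raise LocalizationError("anticodon window extends past called bases")
    # antiparallel reversal: tRNA base 34 pairs the *last* base of the
    # sequenced triplet
    return TraceLocus(anticodon_window=window, trace_index=window[2])


# ---------------------------------------------------------------------------
# Peak quantification
# ---------------------------------------------------------------------------


def _local_half_spacing(ploc: np.ndarray, i: int) -> tuple[float, float]:
    if len(ploc) == 1:
        return 6.0, 6.0  # lone peak: fall back to a nominal window
    left = (ploc[i] - ploc[i - 1]) / 2.0 if i > 0 else (ploc[i + 1] - ploc[i]) / 2.0
    right = (
        (ploc[i + 1] - ploc[i]) / 2.0 if i < len(ploc) - 1 else (ploc[i] - ploc[i - 1]) / 2.0
    )
    return left, right


def integrate_peak(
    chrom: Chromatogram, trace_index: int, method: str = "area"
) -> PeakAreas:
    """Baseline-subtracted per-channel signal at one called peak.

    The window is centred on the peak location and extends half the local
    inter-peak spacing on each side.  Each channel's baseline is its
    ``BASELINE_PERCENTILE`` (5th) percentile over the whole trace,
    subtracted per sample with negatives clamped to zero, then integrated
    trapezoidally (``method="area"``) or read at the apex
    (``method="height"``).
    """
    ploc = chrom.peak_locations
    if not 0 <= trace_index < len(ploc):
        raise DomainError(
            f"trace_index {trace_index} outside 0..{len(ploc) - 1}"
        )
    if method not in ("area", "height"):
        raise DomainError(f"unknown peak measurement method {method!r}")
    center = int(ploc[trace_index])
    half_left, half_right = _local_half_spacing(ploc, trace_index)
    lo = int(round(center - half_left))
    hi = int(round(center + half_right))
    n = chrom.n_samples
    if lo < 0 or hi > n - 1:
        warnings.warn(
            "integration window truncated at trace boundary", stacklevel=2
        )
        lo, hi = max(lo, 0), min(hi, n - 1)

    areas = {}
    for base in DNA_BASES:
        signal = np.asarray(chrom.channels[base], dtype=float)
        baseline = np.percentile(signal, BASELINE_PERCENTILE)
        segment = np.clip(signal[lo : hi + 1] - baseline, 0.0, None)
        if method == "area":
            areas[base] = float(np.trapezoid(segment))
        else:
            areas[base] = float(np.clip(signal[center] - baseline, 0.0, None))
    return PeakAreas(areas=areas, window=(lo, hi))


def estimate_inosine_fraction(areas: PeakAreas) -> float:
    """Modified fraction = C / (C + T) signal at the position pairing tRNA
    base 34 (A and G channels are reported but do not enter the estimate)."""
    t, c = areas["T"], areas["C"]
    if t + c <= 0:
        raise NoSignalError("no T or C signal at the anticodon position")
    return c / (c + t)


def call_modification(
    fraction: float,
    baseline_noise_mean: float,
    baseline_noise_sd: float,
    threshold: float = DEFAULT_MODIFICATION_THRESHOLD,
) -> InosineCall:
    """Call inosine modification from an estimated fraction.

    Two gates must both pass: the fraction reaches the absolute visibility
    threshold (~5% is clearly evident in a chromatogram), and it clears the
    trace's own baseline C/(C+T) noise by 3 standard deviations, so a noisy
    baseline is never called modified.
    """
    for name, v in (
        ("fraction", fraction),
        ("baseline_noise_mean", baseline_noise_mean),
        ("baseline_noise_sd", baseline_noise_sd),
        ("threshold", threshold),
    ):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must be in [0,1], got {v}")
    modified = fraction >= threshold and fraction >= (
        baseline_noise_mean + 3.0 * baseline_noise_sd
    )
    return InosineCall(
        fraction=fraction,
        baseline_noise_mean=baseline_noise_mean,
        baseline_noise_sd=baseline_noise_sd,
        modified=modified,
        threshold=threshold,
    )


def background_fraction_stats(
    chrom: Chromatogram,
    exclude: tuple[int, ...] = (),
    method: str = "area",
) -> tuple[float, float]:
    """Baseline C/(C+T) statistics from unambiguous T positions.

    Every called-T peak outside ``exclude`` yields one background fraction
    measurement; the mean and sample sd of those characterize how large a
    spurious C share the trace produces at genuinely unmodified positions.
    """
    fractions = []
    for i, base in enumerate(chrom.called_bases):
        if base != "T" or i in exclude:
            continue
        areas = integrate_peak(chrom, i, method=method)
        t, c = areas["T"], areas["C"]
        if t + c > 0:
            fractions.append(c / (c + t))
    if not fractions:
        raise NoSignalError("no background T positions available")
    arr = np.asarray(fractions)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd
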