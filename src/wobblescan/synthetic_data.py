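"""Synthetic chromatograms, synthetic screen replicates, and the packaged
reference dataset.

Everything the pipeline consumes can be generated here so every stage is
testable without external downloads:

* :func:`simulate_trace` renders a DNA sequence as a four-channel
  electropherogram of Gaussian peaks with optional mixed-base positions
  (e.g. a T/C mixture at the position complementary to a partially
  inosine-modified A34), plus baseline and Gaussian noise.
* :func:`write_abif` serializes a chromatogram as a minimal but valid ABIF
  (.ab1) container readable by standard ABIF parsers.
* :func:`simulate_screen` draws replicate fluorescence measurements around a
  true reassignment efficiency between 0%/100% reference anchors.
* :func:`reference_dataset` loads the packaged per-anticodon measurements of
  the 15-anticodon A34 study (reassignment efficiencies with censoring, plus
  the inosine-modified fraction each anticodon showed).

The default trace morphology (12-sample peak spacing, sigma 2.5, amplitude
1000, baseline 20, noise sd 10) mimics a typical analyzed capillary trace;
all parameters are overridable per spec.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetic_code
from .errors import SpecError, TraceFormatError
from .screen_quant import REF0, REF100, SAMPLE, RawMeasurement
from .trace_quant import DNA_BASES, Chromatogram

# ---------------------------------------------------------------------------
# Synthetic chromatograms
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTraceSpec:
    """Parameters of one synthetic electropherogram.

    ``mixed_positions`` maps a base index in ``sequence`` to a per-base
    fraction map summing to 1 (amplitude is split accordingly).  With
    ``quantize`` the signal is rounded to integer counts, matching real
    analyzed trace data and making ABIF round-trips lossless.
    """

    sequence: str
    mixed_positions: dict[int, dict[str, float]] = field(default_factory=dict)
    peak_spacing: int = 12
    peak_sigma: float = 2.5
    amplitude: float = 1000.0
    baseline_level: float = 20.0
    noise_sd: float = 10.0
    seed: int = 0
    quantize: bool = True

    def validate(self) -> None:
        seq = self.sequence.upper()
        if not seq or any(b not in DNA_BASES for b in seq):
            raise SpecError(f"sequence must be non-empty DNA, got {self.sequence!r}")
        if not 0 < self.peak_sigma < self.peak_spacing:
            raise SpecError(
                f"need 0 < peak_sigma ({self.peak_sigma}) < peak_spacing "
                f"({self.peak_spacing})"
            )
        for idx, fractions in self.mixed_positions.items():
            if not 0 <= idx < len(seq):
                raise SpecError(f"mixed position {idx} outside sequence")
            total = sum(fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise SpecError(
                    f"fractions at position {idx} sum to {total}, not 1"
                )
            if any(b not in DNA_BASES for b in fractions):
                raise SpecError(f"invalid base in fractions at position {idx}")
            if any(f < 0 for f in fractions.values()):
                raise SpecError(f"negative fraction at position {idx}")


def simulate_trace(spec: SyntheticTraceSpec) -> Chromatogram:
    """Render a :class:`SyntheticTraceSpec` into a chromatogram.

    Base ``i`` contributes a Gaussian peak centred at
    ``(i + 1) * peak_spacing`` to its channel (split across channels at
    mixed positions); baseline and seeded Gaussian noise are added to all
    channels and the signal is clipped at zero.  Peak locations are the
    centres; called bases are the majority base per position (ties broken
    in ACGT order).  Deterministic for a fixed seed.
    """
    spec.validate()
    seq = spec.sequence.upper()
    n_bases = len(seq)
    spacing = spec.peak_spacing
    centers = np.arange(1, n_bases + 1) * spacing
    n_samples = (n_bases + 2) * spacing
    x = np.arange(n_samples, dtype=float)

    channels = {b: np.zeros(n_samples) for b in DNA_BASES}
    called = []
    for i, base in enumerate(seq):
        fractions = spec.mixed_positions.get(i, {base: 1.0})
        shape = np.exp(-((x - centers[i]) ** 2) / (2.0 * spec.peak_sigma**2))
        for b, f in fractions.items():
            if f > 0:
                channels[b] += f * spec.amplitude * shape
        called.append(max(fractions, key=lambda b: (fractions[b], -DNA_BASES.index(b))))

    rng = np.random.default_rng(spec.seed)
    for b in DNA_BASES:
        signal = channels[b] + spec.baseline_level
        if spec.noise_sd > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd, size=n_samples)
        signal = np.clip(signal, 0.0, None)
        if spec.quantize:
            signal = np.rint(signal)
        channels[b] = signal

    return Chromatogram(
        channels=channels,
        peak_locations=centers,
        called_bases="".join(called),
    )


# ---------------------------------------------------------------------------
# Minimal ABIF writer
# ---------------------------------------------------------------------------

_ABIF_VERSION = 101
_HEADER_SIZE = 128
_DIR_ENTRY = struct.Struct(">4sIHHIIII")  # name, number, type, size, n, bytes, offset, handle
_TYPE_CHAR = 2
_TYPE_SHORT = 4


def _short_array(values) -> bytes:
    out = []
    for v in values:
        iv = int(round(float(v)))
        if not -32768 <= iv <= 32767:
            raise TraceFormatError(
                f"signal value {iv} does not fit a 16-bit ABIF data point"
            )
        out.append(iv)
    return struct.pack(f">{len(out)}h", *out)


def write_abif(chrom: Chromatogram) -> bytes:
    """Serialize a chromatogram as a minimal ABIF container.

    Writes the analyzed-data tags standard readers expect: DATA9-12 in
    ``channel_order``, PLOC1/2, PBAS1/2 and FWO_.  Signal is stored as
    16-bit integers (values are rounded; out-of-range values error).
    """
    chrom.validate()
    if len(chrom.peak_locations) == 0:
        raise TraceFormatError("refusing to write a chromatogram with no peaks")

    order = chrom.channel_order
    tags: list[tuple[bytes, int, int, int, int, bytes]] = []

    def add(name: str, number: int, elem_type: int, elem_size: int, n: int, data: bytes):
        tags.append((name.encode(), number, elem_type, elem_size, n, data))

    for i, base in enumerate(order):
        data = _short_array(chrom.channels[base])
        add("DATA", 9 + i, _TYPE_SHORT, 2, len(chrom.channels[base]), data)
    ploc = _short_array(chrom.peak_locations)
    add("PLOC", 1, _TYPE_SHORT, 2, len(chrom.peak_locations), ploc)
    add("PLOC", 2, _TYPE_SHORT, 2, len(chrom.peak_locations), ploc)
    pbas = chrom.called_bases.encode()
    add("PBAS", 1, _TYPE_CHAR, 1, len(pbas), pbas)
    add("PBAS", 2, _TYPE_CHAR, 1, len(pbas), pbas)
    add("FWO_", 1, _TYPE_CHAR, 1, 4, order.encode())

    blob = bytearray()
    entries = []
    data_cursor = _HEADER_SIZE
    for name, number, elem_type, elem_size, n, data in tags:
        size = len(data)
        if size <= 4:
            # small payloads live inside the directory entry's offset field
            offset_field = int.from_bytes(data.ljust(4, b"\x00"), "big")
            entries.append((name, number, elem_type, elem_size, n, size, offset_field))
        else:
            entries.append((name, number, elem_type, elem_size, n, size, data_cursor))
            blob.extend(data)
            data_cursor += size

    dir_offset = data_cursor
    directory = bytearray()
    for name, number, elem_type, elem_size, n, size, offset_field in entries:
        directory.extend(
            _DIR_ENTRY.pack(name, number, elem_type, elem_size, n, size, offset_field, 0)
        )

    header = b"ABIF" + struct.pack(
        ">H4sI2H3I",
        _ABIF_VERSION,
        b"tdir",
        1,
        1023,  # element type: directory entry
        _DIR_ENTRY.size,
        len(entries),
        len(entries) * _DIR_ENTRY.size,
        dir_offset,
    )
    header = header.ljust(_HEADER_SIZE, b"\x00")
    return bytes(header) + bytes(blob) + bytes(directory)


# ---------------------------------------------------------------------------
# Synthetic screen replicates
# ---------------------------------------------------------------------------


@dataclass
class SyntheticScreenSpec:
    """Parameters of one synthetic screen condition.

    ``true_re`` and ``replicate_sd`` are percent of the reference bracket;
    ``ref0_value``/``ref100_value`` are plate-reader arbitrary units.
    """

    true_re: float
    n_replicates: int = 12
    replicate_sd: float = 0.5
    ref0_value: float = 100.0
    ref100_value: float = 10100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise SpecError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if self.ref100_value <= self.ref0_value:
            raise SpecError("ref100_value must exceed ref0_value")
        if self.replicate_sd < 0:
            raise SpecError("replicate_sd must be >= 0")


def simulate_screen(spec: SyntheticScreenSpec) -> list[RawMeasurement]:
    """Draw replicate fluorescence values around a true reassignment
    efficiency, with the paired reference wells emitted alongside.

    Sample values are ``ref0 + (true_re + e)/100 * span`` with
    ``e ~ N(0, replicate_sd)``; the references are emitted at their exact
    anchor values.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    span = spec.ref100_value - spec.ref0_value
    out = []
    for i in range(spec.n_replicates):
        rid = f"r{i + 1}"
        noise = rng.normal(0.0, spec.replicate_sd) if spec.replicate_sd > 0 else 0.0
        value = spec.ref0_value + (spec.true_re + noise) / 100.0 * span
        out.append(RawMeasurement(max(value, 0.0), rid, SAMPLE))
        out.append(RawMeasurement(spec.ref0_value, rid, REF0))
        out.append(RawMeasurement(spec.ref100_value, rid, REF100))
    return out


# ---------------------------------------------------------------------------
# Packaged reference dataset
# ---------------------------------------------------------------------------

CENSORED = "BD"  # below the screen's limit of detection
NOT_EVALUATED = "NE"

MEASURED = "measured"


@dataclass(frozen=True)
class FixtureMeasurement:
    """One efficiency cell: value +/- sd (percent) or a censoring status."""

    value: float | None
    sd: float | None
    status: str  # "measured" | "censored" | "not_evaluated"

    @property
    def is_measured(self) -> bool:
        return self.status == MEASURED


@dataclass(frozen=True)
class FixtureRow:
    """Per-anticodon record: efficiencies by codon third base, the
    targeted codon, and the observed inosine-modified fraction."""

    anticodon: str
    amino_acid: str
    codon: str
    re: dict[str, FixtureMeasurement] = field(hash=False)
    modification_fraction: float = 0.0
    printed_ratio: str | None = None


@dataclass(frozen=True)
class ReferenceDataset:
    """The 15-anticodon A34 reassignment study as a fixture."""

    rows: tuple[FixtureRow, ...]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, anticodon: str) -> FixtureRow:
        for r in self.rows:
            if r.anticodon == anticodon:
                return r
        raise KeyError(anticodon)


def _cell(value, sd) -> FixtureMeasurement:
    if isinstance(value, str):
        value = value.strip()
    if value in (CENSORED,):
        return FixtureMeasurement(None, None, "censored")
    if value in (NOT_EVALUATED, "", None) or (
        isinstance(value, float) and math.isnan(value)
    ):
        return FixtureMeasurement(None, None, "not_evaluated")
    sd_val = None
    if sd is not None and not (isinstance(sd, float) and math.isnan(sd)):
        sd_val = float(sd)
    return FixtureMeasurement(float(value), sd_val, MEASURED)


def reference_dataset() -> ReferenceDataset:
    """Load the packaged per-anticodon reference measurements.

    Fifteen A34 anticodons with reassignment efficiencies at the U-, C-,
    A- and G-ending codons of each box (censored cells flagged, unevaluated
    cells marked) and the inosine-modified fraction observed by sequencing
    (1.0 for ACG, 0.5 for AUG, 0.15 for AAG, 0 elsewhere).
    """
    with resources.files("wobblescan.data").joinpath(
        "reassignment_reference.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    rows = []
    for rec in df.itertuples(index=False):
        re_map = {
            "U": _cell(rec.re_u, rec.sd_u),
            "C": _cell(rec.re_c, rec.sd_c),
            "A": _cell(rec.re_a, rec.sd_a),
            "G": _cell(rec.re_g, rec.sd_g),
        }
        printed = rec.printed_ratio
        if isinstance(printed, float) and math.isnan(printed):
            printed = None
        rows.append(
            FixtureRow(
                anticodon=rec.anticodon,
                amino_acid=rec.amino_acid,
                codon=rec.codon,
                re=re_map,
                modification_fraction=float(rec.mod_fraction),
                printed_ratio=printed,
            )
        )
    return ReferenceDataset(rows=tuple(rows))


def reference_re_table(dataset: ReferenceDataset | None = None) -> pd.DataFrame:
    """Flatten the reference dataset into an aggregated RE table
    (anticodon, codon, mean, sd, n, below_lod) covering measured and
    censored cells; unevaluated cells are omitted.

    Censored cells carry a NaN mean with ``below_lod`` set; downstream
    ratio code substitutes the LOD, never zero.
    """
    if dataset is None:
        dataset = reference_dataset()
    records = []
    for row in dataset:
        box = genetic_code.codon_box(row.codon)
        for codon in box.members:
            cell = row.re[codon.third]
            if cell.status == "not_evaluated":
                continue
            records.append(
                {
                    "anticodon": row.anticodon,
                    "codon": codon.bases,
                    "mean": cell.value if cell.is_measured else float("nan"),
                    "sd": cell.sd if cell.sd is not None else 0.0,
                    "n": 12,
                    "below_lod": not cell.is_measured,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Full synthetic datasets mirroring the reference study
# ---------------------------------------------------------------------------

# Synthetic cDNA flanks around the sequenced anticodon triplet.  These are a
# synthetic stand-in for the real tRNA body (which is not part of the
# packaged data); localization is reference-driven, so only uniqueness and
# length matter.
SYNTHETIC_FLANK_LEFT = "GGTGGTAGAGCATTCGACTTCCA"
SYNTHETIC_FLANK_RIGHT = "CTGCCAGGGATCGAACCTGGACC"


def reference_cdna_for(anticodon: str) -> str:
    """Synthetic sequenced-strand cDNA reference for one anticodon, with
    the anticodon triplet (DNA spelling of the targeted codon) marked in
    lowercase."""
    codon = genetic_code.targeted_codon(anticodon)
    triplet = genetic_code.rna_to_dna(codon.bases)
    return SYNTHETIC_FLANK_LEFT + triplet.lower() + SYNTHETIC_FLANK_RIGHT


def simulate_reference_trace(
    anticodon: str,
    modification_fraction: float,
    seed: int = 0,
    **spec_overrides,
) -> tuple[Chromatogram, str]:
    """Synthetic trace for one anticodon at a given inosine-modified
    fraction; returns the chromatogram and its marked cDNA reference.

    The position complementary to tRNA base 34 (third base of the sequenced
    triplet) is rendered as a T/C mixture with C share equal to the
    modified fraction.
    """
    if not 0.0 <= modification_fraction <= 1.0:
        raise SpecError(
            f"modification fraction must be in [0,1], got {modification_fraction}"
        )
    reference = reference_cdna_for(anticodon)
    sequence = reference.upper()
    pos34 = len(SYNTHETIC_FLANK_LEFT) + 2
    mixed = {}
    if modification_fraction > 0:
        mixed[pos34] = {
            "C": modification_fraction,
            "T": 1.0 - modification_fraction,
        }
    spec = SyntheticTraceSpec(
        sequence=sequence, mixed_positions=mixed, seed=seed, **spec_overrides
    )
    return simulate_trace(spec), reference


def simulate_reference_traces(
    seed: int = 0, dataset: ReferenceDataset | None = None, **spec_overrides
) -> dict[str, tuple[Chromatogram, str]]:
    """Synthetic traces for all fixture anticodons at their observed
    modification fractions, each with an independent sub-seed."""
    if dataset is None:
        dataset = reference_dataset()
    out = {}
    for i, row in enumerate(dataset):
        out[row.anticodon] = simulate_reference_trace(
            row.anticodon,
            row.modification_fraction,
            seed=(seed * 1009 + i) % (2**31 - 1),
            **spec_overrides,
        )
    return out


def simulate_reference_screen_table(
    seed: int = 0,
    dataset: ReferenceDataset | None = None,
    n_replicates: int = 12,
    replicate_sd: float = 0.5,
) -> pd.DataFrame:
    """A full synthetic screen table whose true efficiencies are the
    reference dataset's measured means (censored cells simulated at zero
    true reassignment).

    One batch per anticodon/codon condition, with its own reference wells.
    """
    if dataset is None:
        dataset = reference_dataset()
    records = []
    batch_idx = 0
    for row in dataset:
        box = genetic_code.codon_box(row.codon)
        for codon in box.members:
            cell = row.re[codon.third]
            if cell.status == "not_evaluated":
                continue
            true_re = cell.value if cell.is_measured else 0.0
            spec = SyntheticScreenSpec(
                true_re=true_re,
                n_replicates=n_replicates,
                replicate_sd=replicate_sd,
                seed=(seed * 7919 + batch_idx) % (2**31 - 1),
            )
            batch = f"{row.anticodon}-{codon.bases}"
            for m in simulate_screen(spec):
                records.append(
                    {
                        "replicate_id": m.replicate_id,
                        "construct": m.construct,
                        "anticodon": row.anticodon,
                        "codon": codon.bases,
                        "value": m.value,
                        "batch": batch,
                    }
                )
            batch_idx += 1
    return pd.DataFrame.from_records(records)


def write_screen_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a screen table as TSV."""
    df.to_csv(path, sep="\t", index=False)
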