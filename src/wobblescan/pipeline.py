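"""End-to-end orchestration: screen -> ratios -> trace calls -> concordance.

The pipeline reproduces the analysis surface of the A34 decoding study as
machine-readable tables: per-(anticodon, codon) reassignment efficiencies
with LOD censoring, per-anticodon U3:C3 discrimination ratios (with censored
floors), per-anticodon inosine-modification calls from Sanger traces, and a
wobble-rule concordance classification of each anticodon's measured decoded
set.

Concordance classes, in precedence order (modification evidence overrides
pairing-only explanations):

``inosine_like``
    The anticodon decodes both U- and C-ending codons and sequencing showed
    inosine modification.
``two_out_of_three``
    A strong box (two G/C prefix bases) decoded at the U-, C- and G-ending
    codons or better.
``wobble_consistent``
    Exactly the original-wobble-rules prediction (the U-ending codon only).
``anomalous``
    Anything else; raw ratios are reported for human judgment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genetic_code, screen_quant, trace_quant
from .discrimination_stats import (
    DEFAULT_LOD,
    discrimination_floor,
    discrimination_ratio,
    format_ratio,
)
from .errors import ConfigError, DomainError, WobblescanError
from .trace_quant import DEFAULT_MODIFICATION_THRESHOLD

CLASS_INOSINE_LIKE = "inosine_like"
CLASS_TWO_OUT_OF_THREE = "two_out_of_three"
CLASS_WOBBLE_CONSISTENT = "wobble_consistent"
CLASS_ANOMALOUS = "anomalous"


@dataclass
class AnalysisConfig:
    """File-driven configuration for the command-line pipeline."""

    screen_table: str | None = None
    traces: list[dict] = field(default_factory=list)
    out_dir: str = "."
    lod: float = DEFAULT_LOD
    detection_multiple: float = 2.0
    modification_threshold: float = DEFAULT_MODIFICATION_THRESHOLD
    rule_sets: list[str] = field(
        default_factory=lambda: ["crick_original", "two_out_of_three", "inosine"]
    )
    rule_set_overrides: str | None = None
    flank: int = 12
    max_edit_distance: int = 5
    peak_method: str = "area"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        try:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if cfg.lod <= 0:
            raise ConfigError(f"lod must be positive, got {cfg.lod}")
        return cfg


# ---------------------------------------------------------------------------
# Screen stage
# ---------------------------------------------------------------------------


def ratios_from_re_table(
    re_df: pd.DataFrame, lod: float = DEFAULT_LOD
) -> pd.DataFrame:
    """Per-anticodon U3:C3 discrimination ratios from an aggregated RE table.

    For each anticodon the U-ending row of its targeted codon's box supplies
    RE_U; the C-ending row supplies RE_C unless censored (or absent), in
    which case the LOD-substituted floor is used.  Ratios come from
    aggregated means, not per-replicate values.
    """
    records = []
    for anticodon, sub in re_df.groupby("anticodon", sort=False):
        target = genetic_code.targeted_codon(anticodon)
        prefix = target.prefix
        u_codon = prefix + "U"
        c_codon = prefix + "C"
        by_codon = {r.codon: r for r in sub.itertuples(index=False)}
        u_row = by_codon.get(u_codon)
        if u_row is None or bool(u_row.below_lod):
            # no usable U-ending efficiency: the ratio is undefined
            continue
        re_u = float(u_row.mean)
        c_row = by_codon.get(c_codon)
        if c_row is None or bool(c_row.below_lod):
            dr = discrimination_floor(re_u, lod=lod)
            re_c = np.nan
        else:
            re_c = float(c_row.mean)
            dr = discrimination_ratio(re_u, re_c)
        records.append(
            {
                "anticodon": anticodon,
                "codon_u": u_codon,
                "codon_c": c_codon,
                "re_u": re_u,
                "re_c": re_c,
                "u_share": dr.u_share,
                "c_share": dr.c_share,
                "is_floor": dr.is_floor,
                "ratio": format_ratio(dr),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "anticodon",
            "codon_u",
            "codon_c",
            "re_u",
            "re_c",
            "u_share",
            "c_share",
            "is_floor",
            "ratio",
        ],
    )


def run_screen_analysis(
    screen: pd.DataFrame | str | Path,
    lod: float = DEFAULT_LOD,
    batch_col: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw screen table -> (aggregated RE table, discrimination-ratio table)."""
    if not isinstance(screen, pd.DataFrame):
        screen = screen_quant.read_screen_table(screen)
    re_df = screen_quant.analyze_screen_table(screen, lod=lod, batch_col=batch_col)
    ratio_df = ratios_from_re_table(re_df, lod=lod)
    return re_df, ratio_df


# ---------------------------------------------------------------------------
# Trace stage
# ---------------------------------------------------------------------------


def analyze_trace(
    chrom: trace_quant.Chromatogram,
    reference_cdna: str,
    flank: int = 12,
    max_edit_distance: int = 5,
    threshold: float = DEFAULT_MODIFICATION_THRESHOLD,
    peak_method: str = "area",
) -> trace_quant.InosineCall:
    """Quantify inosine modification at position 34 in one trace.

    Locates the sequenced anticodon triplet, measures baseline-subtracted
    T/C signal at its third base, and calls modification against the
    trace's own background C/(C+T) noise at unambiguous T positions.
    """
    locus = trace_quant.locate_anticodon(
        chrom, reference_cdna, flank=flank, max_edit_distance=max_edit_distance
    )
    areas = trace_quant.integrate_peak(chrom, locus.trace_index, method=peak_method)
    fraction = trace_quant.estimate_inosine_fraction(areas)
    noise_mean, noise_sd = trace_quant.background_fraction_stats(
        chrom, exclude=locus.anticodon_window, method=peak_method
    )
    return trace_quant.call_modification(
        fraction, noise_mean, noise_sd, threshold=threshold
    )


def run_trace_analysis(
    traces: dict[str, tuple[trace_quant.Chromatogram | str | Path, str]],
    flank: int = 12,
    max_edit_distance: int = 5,
    threshold: float = DEFAULT_MODIFICATION_THRESHOLD,
    peak_method: str = "area",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-sample modification calls for a set of traces.

    ``traces`` maps a sample name (typically the anticodon) to a
    ``(chromatogram or path, marked reference cDNA)`` pair.  Per-file parse
    and localization failures are collected and returned alongside the
    table; the run continues past them.
    """
    records = []
    errors: dict[str, str] = {}
    for name, (source, reference) in traces.items():
        try:
            chrom = (
                source
                if isinstance(source, trace_quant.Chromatogram)
                else trace_quant.read_trace(source)
            )
        except OSError as exc:
            errors[name] = f"cannot read trace: {exc}"
            continue
        except WobblescanError as exc:
            errors[name] = str(exc)
            continue
        try:
            call = analyze_trace(
                chrom,
                reference,
                flank=flank,
                max_edit_distance=max_edit_distance,
                threshold=threshold,
                peak_method=peak_method,
            )
        except WobblescanError as exc:
            errors[name] = str(exc)
            continue
        records.append(
            {
                "sample": name,
                "fraction": call.fraction,
                "baseline_noise_mean": call.baseline_noise_mean,
                "baseline_noise_sd": call.baseline_noise_sd,
                "modified": call.modified,
                "threshold": call.threshold,
            }
        )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "sample",
            "fraction",
            "baseline_noise_mean",
            "baseline_noise_sd",
            "modified",
            "threshold",
        ],
    )
    return df, errors


# ---------------------------------------------------------------------------
# Concordance stage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceRecord:
    """Measured decoded set vs. wobble-rule predictions for one anticodon."""

    anticodon: str
    measured: tuple[str, ...]
    predicted: dict[str, tuple[str, ...]] = field(hash=False)
    classification: str = CLASS_ANOMALOUS


def _classify(
    measured_thirds: set[str], box_strength: int, modified: bool
) -> str:
    if modified and {"U", "C"} <= measured_thirds:
        return CLASS_INOSINE_LIKE
    if box_strength == 2 and {"U", "C", "G"} <= measured_thirds:
        return CLASS_TWO_OUT_OF_THREE
    if measured_thirds == {"U"}:
        return CLASS_WOBBLE_CONSISTENT
    return CLASS_ANOMALOUS


def wobble_concordance(
    re_df: pd.DataFrame,
    modification: dict[str, float] | None = None,
    rule_sets: list[str] | None = None,
) -> list[ConcordanceRecord]:
    """Score each anticodon's measured decoded set against wobble-rule
    predictions.

    The measured set holds the codons decoded above the LOD
    (``below_lod == False``); ``modification`` maps anticodons to observed
    inosine fractions (treated as modified when > 0).
    """
    if rule_sets is None:
        rule_sets = ["crick_original", "two_out_of_three", "inosine"]
    modification = modification or {}
    records = []
    for anticodon, sub in re_df.groupby("anticodon", sort=False):
        target = genetic_code.targeted_codon(anticodon)
        box = genetic_code.codon_box(target)
        box_codons = {c.bases for c in box.members}
        measured = tuple(
            r.codon
            for r in sub.itertuples(index=False)
            if not bool(r.below_lod)
        )
        outside = set(measured) - box_codons
        if outside:
            raise DomainError(
                f"measured codons {sorted(outside)} outside the {box.prefix}N "
                f"box of anticodon {anticodon}"
            )
        modified = modification.get(anticodon, 0.0) > 0.0
        wobble = "I" if modified else genetic_code.Anticodon(anticodon).wobble
        predicted = {}
        for name in rule_sets:
            rules = genetic_code.get_rule_set(name)
            predicted[name] = tuple(
                c.bases
                for c in genetic_code.predicted_codon_set(wobble, box, rules)
            )
        thirds = {c[2] for c in measured}
        records.append(
            ConcordanceRecord(
                anticodon=anticodon,
                measured=measured,
                predicted=predicted,
                classification=_classify(thirds, box.strength, modified),
            )
        )
    return records


def concordance_table(records: list[ConcordanceRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "anticodon": rec.anticodon,
            "measured": ",".join(rec.measured),
            "classification": rec.classification,
        }
        for name, codons in rec.predicted.items():
            row[f"predicted_{name}"] = ",".join(codons)
        rows.append(row)
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_all(config: AnalysisConfig) -> dict:
    """Run every configured stage and write reports under ``out_dir``.

    Returns a summary dict (also written as ``summary.json``).  Trace-stage
    data errors are recorded in the summary; the caller decides the exit
    status.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.rule_set_overrides:
        genetic_code.load_rule_sets(config.rule_set_overrides)

    summary: dict = {"errors": {}, "outputs": []}

    modification: dict[str, float] = {}
    if config.traces:
        traces = {}
        for entry in config.traces:
            try:
                name = entry["sample"]
                path = entry["file"]
                reference = entry["reference_cdna"]
            except (KeyError, TypeError) as exc:
                raise ConfigError(
                    f"trace entries need sample/file/reference_cdna: {entry}"
                ) from exc
            try:
                if Path(reference).is_file():
                    reference = Path(reference).read_text().strip()
            except OSError:
                pass  # inline sequence too long to be a path
            traces[name] = (path, reference)
        calls_df, errors = run_trace_analysis(
            traces,
            flank=config.flank,
            max_edit_distance=config.max_edit_distance,
            threshold=config.modification_threshold,
            peak_method=config.peak_method,
        )
        calls_df.to_csv(out_dir / "modification_calls.tsv", sep="\t", index=False)
        summary["outputs"].append("modification_calls.tsv")
        summary["errors"].update(errors)
        summary["n_modified"] = int(calls_df["modified"].sum())
        modification = {
            r.sample: float(r.fraction)
            for r in calls_df.itertuples(index=False)
            if bool(r.modified)
        }

    if config.screen_table:
        if not Path(config.screen_table).is_file():
            raise ConfigError(f"screen table not found: {config.screen_table}")
        re_df, ratio_df = run_screen_analysis(config.screen_table, lod=config.lod)
        re_df.to_csv(out_dir / "re_table.tsv", sep="\t", index=False)
        ratio_df.to_csv(out_dir / "ratios.tsv", sep="\t", index=False)
        summary["outputs"] += ["re_table.tsv", "ratios.tsv"]
        summary["n_conditions"] = int(len(re_df))
        summary["n_censored"] = int(re_df["below_lod"].sum())

        records = wobble_concordance(
            re_df, modification=modification, rule_sets=config.rule_sets
        )
        concordance_table(records).to_csv(
            out_dir / "concordance.tsv", sep="\t", index=False
        )
        summary["outputs"].append("concordance.tsv")
        summary["classifications"] = {
            rec.anticodon: rec.classification for rec in records
        }

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    summary["outputs"].append("summary.json")
    return summary
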