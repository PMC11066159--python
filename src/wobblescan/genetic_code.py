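"""Codon/anticodon algebra, codon-box classification, and wobble-rule decoding.

The codon and anticodon are both written 5'->3' in the RNA alphabet.  They
pair antiparallel, so anticodon position 34 (the 5'-most anticodon base, the
wobble position) reads codon position 3, 35 reads 2, and 36 reads 1.  A codon
"box" is the set of four codons sharing their first two bases; boxes whose
prefix contains two G/C bases are "strong" (three base-pair hydrogen-bonding
at both fixed positions), which matters for two-out-of-three decoding.

Wobble-rule sets map the base at anticodon position 34 to the ordered list of
codon third bases it can read, strongest pairing first.  Four rule sets ship
with the package:

``crick_original``
    A reads only U; inosine (I) reads U, C and A.
``expanded_a34``
    Unmodified A34 reads U > C > G > A, in that preference order.
``inosine``
    The behaviour of an I34 anticodon (U, C, A) with unmodified A kept at U.
``two_out_of_three``
    Like the original rules, except that in a strong box (two G/C prefix
    bases) the first two codon positions carry the decoding and all four
    codons of the box are read.

Rule sets can be overridden or extended from a YAML/JSON-style mapping via
:func:`load_rule_sets`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import AlphabetError

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"
#: Inosine, a deaminated adenosine, valid only at anticodon position 34.
INOSINE = "I"

_RNA_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
_DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Codon third bases in standard genetic-code table order.
_THIRD_BASE_ORDER = "UCAG"


def rna_to_dna(seq: str) -> str:
    """Transcribe an RNA string to its DNA spelling (U -> T)."""
    return seq.replace("U", "T").replace("u", "t")


def dna_to_rna(seq: str) -> str:
    """Spell a DNA string as RNA (T -> U)."""
    return seq.replace("T", "U").replace("t", "u")


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement of a DNA string."""
    try:
        return "".join(_DNA_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise AlphabetError(f"not a DNA base: {exc.args[0]!r}") from exc


def _check_rna_triple(bases: str, *, allow_inosine_at: int | None = None) -> None:
    if len(bases) != 3:
        raise AlphabetError(f"expected 3 bases, got {bases!r}")
    for i, b in enumerate(bases):
        if b in RNA_BASES:
            continue
        if b == INOSINE and i == allow_inosine_at:
            continue
        raise AlphabetError(
            f"invalid RNA base {b!r} at position {i + 1} of {bases!r}"
        )


@dataclass(frozen=True)
class Codon:
    """An mRNA codon, 5'->3', positions 1-3 (3 = wobble position)."""

    bases: str

    def __post_init__(self) -> None:
        _check_rna_triple(self.bases)

    @property
    def prefix(self) -> str:
        """First two bases (the box-defining prefix)."""
        return self.bases[:2]

    @property
    def third(self) -> str:
        """The wobble-position base."""
        return self.bases[2]

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class Anticodon:
    """A tRNA anticodon, 5'->3', positions 34-36.

    Position 34 is the wobble base.  The extension base ``I`` (inosine) is
    accepted at position 34 only.
    """

    bases: str

    def __post_init__(self) -> None:
        _check_rna_triple(self.bases, allow_inosine_at=0)

    @property
    def wobble(self) -> str:
        """The base at position 34."""
        return self.bases[0]

    def __str__(self) -> str:
        return self.bases


@dataclass(frozen=True)
class CodonBox:
    """The four codons sharing a two-base prefix.

    ``strength`` counts G/C bases in the prefix: 2 = strong box, 0 = weak.
    """

    prefix: str
    members: tuple[Codon, Codon, Codon, Codon]
    strength: int


@dataclass(frozen=True)
class WobbleRuleSet:
    """A named mapping from anticodon-34 base to readable codon third bases.

    ``mapping`` values are ordered strongest pairing first.  When
    ``box_strength_gate`` is set, boxes whose strength reaches the gate are
    decoded completely regardless of the wobble base (two-out-of-three
    decoding).
    """

    name: str
    mapping: dict[str, tuple[str, ...]] = field(hash=False)
    box_strength_gate: int | None = None

    def __post_init__(self) -> None:
        for wobble, thirds in self.mapping.items():
            if wobble not in RNA_BASES + INOSINE:
                raise AlphabetError(f"invalid wobble base {wobble!r}")
            if len(set(thirds)) != len(thirds):
                raise AlphabetError(
                    f"duplicate codon-3 base in rule {self.name}/{wobble}"
                )
            for t in thirds:
                if t not in RNA_BASES:
                    raise AlphabetError(f"invalid codon-3 base {t!r}")


_CRICK_MAPPING = {
    "A": ("U",),
    "C": ("G",),
    "G": ("C", "U"),
    "U": ("A", "G"),
    "I": ("U", "C", "A"),
}

CRICK_ORIGINAL = WobbleRuleSet("crick_original", dict(_CRICK_MAPPING))
EXPANDED_A34 = WobbleRuleSet(
    "expanded_a34", {**_CRICK_MAPPING, "A": ("U", "C", "G", "A")}
)
INOSINE_RULES = WobbleRuleSet("inosine", {"I": ("U", "C", "A"), "A": ("U",)})
TWO_OUT_OF_THREE = WobbleRuleSet(
    "two_out_of_three", dict(_CRICK_MAPPING), box_strength_gate=2
)

RULE_SETS: dict[str, WobbleRuleSet] = {
    rs.name: rs
    for rs in (CRICK_ORIGINAL, EXPANDED_A34, INOSINE_RULES, TWO_OUT_OF_THREE)
}


def get_rule_set(name: str) -> WobbleRuleSet:
    """Look up a registered rule set by name."""
    try:
        return RULE_SETS[name]
    except KeyError:
        raise KeyError(
            f"unknown rule set {name!r}; known: {sorted(RULE_SETS)}"
        ) from None


def load_rule_sets(source) -> dict[str, WobbleRuleSet]:
    """Load rule-set overrides from a YAML file, file path, or mapping.

    Each top-level key is a rule-set name; its value maps wobble bases to
    ordered lists of codon third bases, with an optional
    ``box_strength_gate`` key.  Returns the loaded rule sets (they are also
    registered in :data:`RULE_SETS`).
    """
    if isinstance(source, dict):
        doc = source
    else:
        if hasattr(source, "read"):
            doc = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
    loaded = {}
    for name, body in doc.items():
        body = dict(body)
        gate = body.pop("box_strength_gate", None)
        mapping = {w: tuple(t) for w, t in body.items()}
        rs = WobbleRuleSet(name, mapping, box_strength_gate=gate)
        RULE_SETS[name] = rs
        loaded[name] = rs
    return loaded


def targeted_codon(anticodon: Anticodon | str) -> Codon:
    """The codon read by full Watson-Crick pairing with an anticodon.

    The pairing is antiparallel, so the codon read 5'->3' is the reverse
    complement of the anticodon: position 36 complements codon position 1,
    35 pairs 2, and 34 pairs 3.
    """
    if not isinstance(anticodon, Anticodon):
        anticodon = Anticodon(anticodon)
    try:
        comp = "".join(_RNA_COMPLEMENT[b] for b in reversed(anticodon.bases))
    except KeyError as exc:
        raise AlphabetError(
            f"cannot Watson-Crick pair base {exc.args[0]!r}"
        ) from exc
    return Codon(comp)


def anticodon_for(codon: Codon | str) -> Anticodon:
    """The anticodon whose Watson-Crick target is ``codon`` (inverse of
    :func:`targeted_codon`)."""
    if not isinstance(codon, Codon):
        codon = Codon(codon)
    comp = "".join(_RNA_COMPLEMENT[b] for b in reversed(codon.bases))
    return Anticodon(comp)


def codon_box(codon: Codon | str) -> CodonBox:
    """The codon box (shared two-base prefix) containing ``codon``."""
    if not isinstance(codon, Codon):
        codon = Codon(codon)
    prefix = codon.prefix
    members = tuple(Codon(prefix + b) for b in _THIRD_BASE_ORDER)
    strength = sum(1 for b in prefix if b in "GC")
    return CodonBox(prefix=prefix, members=members, strength=strength)


def predicted_codon_set(
    wobble34: str,
    box: CodonBox,
    rules: WobbleRuleSet | str,
) -> list[Codon]:
    """Codons within ``box`` predicted to be read by a tRNA with ``wobble34``
    at anticodon position 34, in preference order (strongest first).

    Under a gated rule set (two-out-of-three), a box whose strength reaches
    the gate is returned in full, ordered U, C, G, A.
    """
    if isinstance(rules, str):
        rules = get_rule_set(rules)
    if wobble34 not in RNA_BASES + INOSINE:
        raise AlphabetError(f"invalid wobble base {wobble34!r}")
    if (
        rules.box_strength_gate is not None
        and box.strength >= rules.box_strength_gate
    ):
        allowed: tuple[str, ...] = ("U", "C", "G", "A")
    else:
        allowed = rules.mapping.get(wobble34, ())
    return [Codon(box.prefix + third) for third in allowed]
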