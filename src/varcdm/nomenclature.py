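"""Gene-symbol canonicalization and HGVS protein nomenclature.

Gene symbols are resolved against an HGNC table (a bundled subset covering
the default 49-gene lung-cancer panel plus common aliases; a full HGNC TSV
can be supplied instead).  HGVS protein expressions are stored using
three-letter amino-acid codes only; one-letter input is expanded on the way
in.  The wildcard residue ``Xaa`` is a *query-side* construct: the pattern
``p.Gly12Xaa`` matches every single-residue substitution at codon 12, which
is how codon-level actionable-mutation classes (e.g. KRAS codon 12) are
grouped.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "AA3",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "HgncTable",
    "UnknownGeneError",
    "HgvsParseError",
    "ProteinChange",
    "expand_protein_hgvs",
    "parse_protein_hgvs",
    "format_protein_hgvs",
    "matches_pattern",
    "FeatureMapping",
    "map_consequence",
    "load_default_hgnc",
    "load_default_feature_mapping",
    "VARIANT_FEATURES",
    "SEQUENCE_ALTERATIONS",
]

ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "U": "Sec", "*": "Ter", "X": "Xaa",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}
#: residue codes legal in observed expressions (Xaa is pattern-only)
AA3 = frozenset(THREE_TO_ONE) - {"Xaa"}
WILDCARD = "Xaa"

VARIANT_FEATURES = (
    "missense", "nonsense", "frameshift", "inframe",
    "splice", "synonymous", "intron", "other",
)
SEQUENCE_ALTERATIONS = ("SNP", "insertion", "deletion", "MNP", "CNV", "translocation")


class UnknownGeneError(KeyError):
    """Raised when a symbol cannot be resolved against the HGNC table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"unknown gene symbol: {self.symbol!r}"


class HgvsParseError(ValueError):
    """HGVS grammar violation; ``position`` is the 0-based offset of the
    first character that could not be consumed."""

    def __init__(self, expr: str, position: int, message: str):
        super().__init__(f"{message} in {expr!r} at position {position}")
        self.expr = expr
        self.position = position


class HgncTable:
    """Case-insensitive symbol/alias -> (canonical symbol, HGNC accession)."""

    def __init__(self, entries: Iterable[tuple[str, str, str]]):
        self._map: dict[str, tuple[str, str]] = {}
        canonical_ids: dict[str, str] = {}
        for symbol, canonical, hgnc_id in entries:
            key = symbol.strip().upper()
            value = (canonical.strip(), hgnc_id.strip())
            if key in self._map and self._map[key][0] != value[0]:
                raise ValueError(
                    f"alias collision: {symbol!r} maps to both "
                    f"{self._map[key][0]!r} and {value[0]!r}"
                )
            self._map[key] = value
            canonical_ids[value[0]] = value[1]
        # every canonical symbol must resolve to itself
        for canonical, hgnc_id in canonical_ids.items():
            self._map.setdefault(canonical.upper(), (canonical, hgnc_id))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HgncTable":
        """Load from a TSV with columns symbol, canonical, hgnc_id
        (header row required, extra columns ignored)."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            entries = [
                (row["symbol"], row["canonical"], row.get("hgnc_id", ""))
                for row in reader
            ]
        return cls(entries)

    def lookup(self, symbol: str) -> tuple[str, str]:
        try:
            return self._map[symbol.strip().upper()]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self._map

    def __len__(self) -> int:
        return len(self._map)


def load_default_hgnc() -> HgncTable:
    """The bundled HGNC subset (49-gene panel plus aliases)."""
    ref = resources.files("varcdm.assets").joinpath("hgnc_subset.tsv")
    with resources.as_file(ref) as path:
        return HgncTable.from_tsv(path)


def normalize_gene_symbol(symbol: str, table: HgncTable) -> tuple[str, str]:
    """Resolve ``symbol`` (case-insensitive, alias-aware) to its canonical
    HGNC symbol and accession.  Idempotent: the canonical symbol resolves
    to itself."""
    return table.lookup(symbol)


# ---------------------------------------------------------------------------
# HGVS protein expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinChange:
    """A parsed HGVS protein-level expression.

    ``kind`` is one of substitution, synonymous, deletion, insertion,
    duplication, delins, frameshift.  ``ref_residue``/``position`` locate
    the (first) affected residue; ranges carry ``end_residue``/
    ``end_position``.  ``alt_residue`` is the replacement residue for
    substitutions (``Xaa`` marks a wildcard pattern) or the new first
    residue of a frameshift; ``inserted`` is the inserted/replacing peptide
    for ins/delins; ``fs_ter`` is the stop offset of a frameshift when
    stated.
    """

    kind: str
    ref_residue: str
    position: int
    end_residue: str | None = None
    end_position: int | None = None
    alt_residue: str | None = None
    inserted: tuple[str, ...] = ()
    fs_ter: int | None = None

    @property
    def is_wildcard(self) -> bool:
        return self.alt_residue == WILDCARD

    def __str__(self) -> str:
        return format_protein_hgvs(self)


_RES3 = r"(?:[A-Z][a-z]{2})"
_SUB_RE = re.compile(rf"p\.({_RES3})(\d+)({_RES3})$")
_SYN_RE = re.compile(rf"p\.({_RES3})(\d+)=$")
_RANGE = rf"({_RES3})(\d+)(?:_({_RES3})(\d+))?"
_DEL_RE = re.compile(rf"p\.{_RANGE}del$")
_DUP_RE = re.compile(rf"p\.{_RANGE}dup$")
_INS_RE = re.compile(rf"p\.({_RES3})(\d+)_({_RES3})(\d+)ins((?:{_RES3})+)$")
_DELINS_RE = re.compile(rf"p\.{_RANGE}delins((?:{_RES3})+)$")
_FS_RE = re.compile(rf"p\.({_RES3})(\d+)({_RES3})?fs(?:Ter(\d+))?$")

_RES3_CODES = "|".join(sorted(THREE_TO_ONE, key=lambda c: (-len(c), c)))
_TOKEN_RE = re.compile(
    r"delins|del|ins|dup|fs|"          # keywords, longest first
    rf"(?:{_RES3_CODES})|"             # valid three-letter residue codes
    r"[A-Z*X]|"                        # one-letter residue (incl. stop, X)
    r"\d+|_|=|\."
)


def _first_bad_position(expr: str) -> int:
    """Offset of the first character the token grammar cannot consume."""
    pos = 2 if expr.startswith("p.") else 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            return pos
        token = m.group(0)
        if len(token) == 3 and token[0].isupper() and token[1:].islower():
            if token not in THREE_TO_ONE:
                return pos
        pos = m.end()
    return len(expr)


def _split_residues(chunk: str, expr: str, offset: int) -> tuple[str, ...]:
    residues = tuple(chunk[i:i + 3] for i in range(0, len(chunk), 3))
    for i, res in enumerate(residues):
        if res not in THREE_TO_ONE or res == WILDCARD:
            raise HgvsParseError(expr, offset + 3 * i, f"invalid residue {res!r}")
    return residues


def _check_res(res: str, expr: str, *, allow_wildcard: bool = False) -> str:
    if res == WILDCARD:
        if allow_wildcard:
            return res
        raise HgvsParseError(expr, expr.find(res), "wildcard Xaa is only legal as the substituted residue")
    if res not in THREE_TO_ONE:
        raise HgvsParseError(expr, expr.find(res), f"unknown residue code {res!r}")
    return res


def parse_protein_hgvs(expr: str) -> ProteinChange:
    """Parse a three-letter-form HGVS protein expression.

    Supported kinds: substitution (incl. stop-gain via ``Ter`` and the
    ``Xaa`` wildcard), synonymous (``=``), deletion, insertion,
    duplication, delins, frameshift (with optional ``Ter`` offset).
    Callers holding one-letter input expand with
    :func:`expand_protein_hgvs` first.
    """
    if not isinstance(expr, str) or not expr.startswith("p."):
        raise HgvsParseError(str(expr), 0, "protein HGVS must start with 'p.'")

    m = _SUB_RE.match(expr)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        _check_res(ref, expr)
        _check_res(alt, expr, allow_wildcard=True)
        return ProteinChange("substitution", ref, pos, alt_residue=alt)

    m = _SYN_RE.match(expr)
    if m:
        ref = _check_res(m.group(1), expr)
        return ProteinChange("synonymous", ref, int(m.group(2)))

    for regex, kind in ((_DEL_RE, "deletion"), (_DUP_RE, "duplication")):
        m = regex.match(expr)
        if m:
            ref, pos = _check_res(m.group(1), expr), int(m.group(2))
            end_ref = _check_res(m.group(3), expr) if m.group(3) else None
            end_pos = int(m.group(4)) if m.group(4) else None
            if end_pos is not None and end_pos < pos:
                raise HgvsParseError(expr, 0, "range end before start")
            return ProteinChange(kind, ref, pos, end_residue=end_ref, end_position=end_pos)

    m = _INS_RE.match(expr)
    if m:
        ref, pos = _check_res(m.group(1), expr), int(m.group(2))
        end_ref, end_pos = _check_res(m.group(3), expr), int(m.group(4))
        if end_pos < pos:
            raise HgvsParseError(expr, 0, "range end before start")
        inserted = _split_residues(m.group(5), expr, m.start(5))
        return ProteinChange("insertion", ref, pos, end_residue=end_ref,
                             end_position=end_pos, inserted=inserted)

    m = _DELINS_RE.match(expr)
    if m:
        ref, pos = _check_res(m.group(1), expr), int(m.group(2))
        end_ref = _check_res(m.group(3), expr) if m.group(3) else None
        end_pos = int(m.group(4)) if m.group(4) else None
        if end_pos is not None and end_pos < pos:
            raise HgvsParseError(expr, 0, "range end before start")
        inserted = _split_residues(m.group(5), expr, m.start(5))
        return ProteinChange("delins", ref, pos, end_residue=end_ref,
                             end_position=end_pos, inserted=inserted)

    m = _FS_RE.match(expr)
    if m:
        ref, pos = _check_res(m.group(1), expr), int(m.group(2))
        alt = _check_res(m.group(3), expr) if m.group(3) else None
        fs_ter = int(m.group(4)) if m.group(4) else None
        return ProteinChange("frameshift", ref, pos, alt_residue=alt, fs_ter=fs_ter)

    raise HgvsParseError(expr, _first_bad_position(expr), "unrecognized HGVS protein expression")


def format_protein_hgvs(change: ProteinChange) -> str:
    """Canonical three-letter text for a :class:`ProteinChange`
    (inverse of :func:`parse_protein_hgvs`)."""
    c = change
    head = f"p.{c.ref_residue}{c.position}"
    rng = head + (f"_{c.end_residue}{c.end_position}" if c.end_position is not None else "")
    if c.kind == "substitution":
        return head + c.alt_residue
    if c.kind == "synonymous":
        return head + "="
    if c.kind == "deletion":
        return rng + "del"
    if c.kind == "duplication":
        return rng + "dup"
    if c.kind == "insertion":
        return rng + "ins" + "".join(c.inserted)
    if c.kind == "delins":
        return rng + "delins" + "".join(c.inserted)
    if c.kind == "frameshift":
        out = head + (c.alt_residue or "") + "fs"
        if c.fs_ter is not None:
            out += f"Ter{c.fs_ter}"
        return out
    raise ValueError(f"unknown change kind {c.kind!r}")


def expand_protein_hgvs(expr: str) -> str:
    """Rewrite an HGVS protein expression using three-letter residue codes.

    One-letter codes are expanded (``p.L858R`` -> ``p.Leu858Arg``); ``*``
    is normalized to ``Ter`` and ``fs*N`` to ``fsTerN``; already-canonical
    input is returned unchanged, so the function is idempotent.
    """
    if not isinstance(expr, str) or not expr.startswith("p."):
        raise HgvsParseError(str(expr), 0, "protein HGVS must start with 'p.'")
    body = expr[2:].strip()
    out: list[str] = []
    pos = 0
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if m is None:
            raise HgvsParseError(expr, pos + 2, "unexpected character")
        token = m.group(0)
        if len(token) == 1 and token in ONE_TO_THREE:
            out.append(ONE_TO_THREE[token])
        elif len(token) == 3 and token[0].isupper() and token[1:].islower():
            if token not in THREE_TO_ONE:
                raise HgvsParseError(expr, pos + 2, f"unknown residue code {token!r}")
            out.append(token)
        else:
            out.append(token)
        pos = m.end()
    expanded = "p." + "".join(out)
    parse_protein_hgvs(expanded)  # reject anything outside the grammar
    return expanded


def matches_pattern(observed: ProteinChange, pattern: ProteinChange) -> bool:
    """True when ``observed`` is an instance of ``pattern``.

    Kinds, reference residue(s) and position(s) must agree exactly; the
    alternate residue must agree literally unless the pattern's alternate
    is the ``Xaa`` wildcard, which matches any substituted residue at that
    codon (substitutions only — never indel or frameshift events).
    """
    if observed.kind != pattern.kind:
        return False
    if (observed.ref_residue, observed.position) != (pattern.ref_residue, pattern.position):
        return False
    if (observed.end_residue, observed.end_position) != (pattern.end_residue, pattern.end_position):
        return False
    if pattern.kind == "substitution" and pattern.is_wildcard:
        return True
    return (observed.alt_residue == pattern.alt_residue
            and observed.inserted == pattern.inserted
            and observed.fs_ter == pattern.fs_ter)


# ---------------------------------------------------------------------------
# Consequence mapping
# ---------------------------------------------------------------------------

class FeatureMapping:
    """Source-vocabulary -> controlled-vocabulary mapping.

    ``consequence`` maps annotation consequence terms (e.g. MAF
    Variant_Classification) to a ``variant_feature`` and an optional
    ``sequence_alteration`` hint; ``structural`` maps structural terms
    (e.g. MAF Variant_Type) to a ``sequence_alteration``.  Lookup is total:
    unmapped terms route to ``other`` / ``None`` with a logged warning.
    """

    def __init__(self,
                 consequence: Mapping[str, tuple[str, str | None]],
                 structural: Mapping[str, str],
                 version: str = "custom"):
        self.version = version
        self.consequence = {}
        for term, (feature, alteration) in consequence.items():
            if feature not in VARIANT_FEATURES:
                raise ValueError(f"unknown variant_feature {feature!r} for {term!r}")
            if alteration is not None and alteration not in SEQUENCE_ALTERATIONS:
                raise ValueError(f"unknown sequence_alteration {alteration!r} for {term!r}")
            self.consequence[term] = (feature, alteration)
        self.structural = {}
        for term, alteration in structural.items():
            if alteration not in SEQUENCE_ALTERATIONS:
                raise ValueError(f"unknown sequence_alteration {alteration!r} for {term!r}")
            self.structural[term.upper()] = alteration

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureMapping":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        consequence = {k: tuple(v) for k, v in raw["consequence"].items()}
        return cls(consequence, raw.get("structural", {}), raw.get("version", "custom"))

    def map_structural(self, term: str) -> str | None:
        if not term:
            return None
        hit = self.structural.get(term.strip().upper())
        if hit is None:
            logger.warning("unmapped structural term %r", term)
        return hit


def load_default_feature_mapping() -> FeatureMapping:
    """The bundled MAF-dialect mapping."""
    ref = resources.files("varcdm.assets").joinpath("feature_mapping.json")
    with resources.as_file(ref) as path:
        return FeatureMapping.from_json(path)


def map_consequence(source_term: str, mapping: FeatureMapping) -> tuple[str, str | None]:
    """Map a source consequence term to ``(variant_feature,
    sequence_alteration-or-None)``; unmapped terms yield ``("other",
    None)`` and log a warning."""
    hit = mapping.consequence.get(source_term)
    if hit is None:
        logger.warning("unmapped consequence term %r -> 'other'", source_term)
        return ("other", None)
    return hit
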