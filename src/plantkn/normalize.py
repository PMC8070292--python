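"""Entity label normalization: raw surface forms to canonical preferred labels.

Biological entities appear in literature under many spellings — Greek
letters ("β-carotene"), species prefixes on gene names ("StAN1" for the
*Solanum tuberosum* anthocyanin 1 gene), gene-family member suffixes
("BCH1", "BCH2"), primes and hash marks in metabolite names, and plain
synonyms.  Normalization collapses these variants onto a single canonical
label per entity so that mentions from different documents land on the same
network node.

The rule pipeline, applied in a fixed order:

1. ``greek_spelling`` — transliterate Greek letters and map spelling
   variants to their American forms;
2. ``strip_marks``    — remove apostrophes/primes and ``#`` notations
   (``flavonoid-3',5'-hydroxylase`` → ``flavonoid-3,5-hydroxylase``);
3. ``uppercase``      — convert to uppercase;
4. ``species_prefix`` — strip a leading genus-species code (St, Le, ...)
   *only if* the remainder is a known label;
5. ``family_suffix``  — strip trailing member digits (``BCH1`` → ``BCH``)
   *only if* the base is a known label;
6. ``ec_lookup``      — expand EC-number references to full enzyme names;

followed by a synonym-table lookup that maps the processed form to its
preferred label.  Unresolvable labels pass through in processed uppercase
form (and are reported on the module logger), so normalization is total.
The "only if known" guards on rules 4-5 keep stripping from mangling
innocent words ("Or" never becomes "O").
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "SynonymTable",
    "NormalizationConfig",
    "Normalizer",
    "SynonymTableError",
    "RULE_NAMES",
    "normalize_label",
    "is_normalized",
]

logger = logging.getLogger(__name__)

RULE_NAMES = (
    "greek_spelling",
    "strip_marks",
    "uppercase",
    "species_prefix",
    "family_suffix",
    "ec_lookup",
)

GREEK_MAP = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "ζ": "zeta",
    "η": "eta",
    "θ": "theta",
    "ι": "iota",
    "κ": "kappa",
    "λ": "lambda",
    "μ": "mu",
    "ν": "nu",
    "ξ": "xi",
    "π": "pi",
    "ρ": "rho",
    "σ": "sigma",
    "τ": "tau",
    "φ": "phi",
    "χ": "chi",
    "ψ": "psi",
    "ω": "omega",
    "Α": "alpha",
    "Β": "beta",
    "Γ": "gamma",
    "Δ": "delta",
    "Ω": "omega",
}

#: British -> American spellings common in plant-science text.
DEFAULT_SPELLING_MAP = {
    "colour": "color",
    "colours": "colors",
    "coloured": "colored",
    "flavour": "flavor",
    "fibre": "fiber",
    "tuberisation": "tuberization",
    "characterised": "characterized",
    "analysed": "analyzed",
    "sulphate": "sulfate",
    "sulphur": "sulfur",
}

#: Apostrophe-like marks and hash notations removed by ``strip_marks``.
_MARKS = "'’′ʹ`#"

_WORD_RE = re.compile(r"[A-Za-z]+")
_EC_RE = re.compile(r"^EC[\s:]*((?:\d+\.){1,3}\d+)$", re.IGNORECASE)
_FAMILY_SUFFIX_RE = re.compile(r"^(.*?[^\s\d])(\d+)$")


class SynonymTableError(ValueError):
    """Raised on malformed or cyclic synonym tables."""


class SynonymTable:
    """Case-insensitive alias → preferred-label map with a source tag per row.

    The table is acyclic: no preferred label may itself be an alias of a
    *different* label (identity rows registering a label as its own
    preferred form are allowed and are the usual way to declare a label
    "known" without renaming it).
    """

    def __init__(self, rows: Iterable[tuple[str, str, str]]) -> None:
        self._alias: dict[str, str] = {}
        self._source: dict[str, str] = {}
        self._preferred: set[str] = set()
        for alias, preferred, source in rows:
            alias_key = alias.strip().upper()
            preferred = preferred.strip().upper()
            if not alias_key or not preferred:
                raise SynonymTableError("empty alias or preferred label")
            if alias_key in self._alias and self._alias[alias_key] != preferred:
                raise SynonymTableError(
                    f"alias {alias_key!r} maps to both "
                    f"{self._alias[alias_key]!r} and {preferred!r}"
                )
            self._alias[alias_key] = preferred
            self._source[alias_key] = source
            self._preferred.add(preferred)
        for preferred in self._preferred:
            target = self._alias.get(preferred)
            if target is not None and target != preferred:
                raise SynonymTableError(
                    f"cycle: preferred label {preferred!r} is an alias of "
                    f"{target!r}"
                )

    @classmethod
    def from_tsv(cls, *paths: str | Path) -> "SynonymTable":
        """Load rows of ``alias<TAB>preferred_label<TAB>source``."""
        rows = []
        for path in paths:
            with open(path, newline="", encoding="utf-8") as handle:
                for line_no, row in enumerate(
                    csv.reader(handle, delimiter="\t"), start=1
                ):
                    if not row or row[0].startswith("#"):
                        continue
                    if len(row) < 2:
                        raise SynonymTableError(
                            f"{path}:{line_no}: expected alias<TAB>preferred"
                        )
                    source = row[2] if len(row) > 2 else ""
                    rows.append((row[0], row[1], source))
        return cls(rows)

    def lookup(self, label: str) -> Optional[str]:
        return self._alias.get(label.upper())

    def resolves(self, label: str) -> bool:
        key = label.upper()
        return key in self._alias or key in self._preferred

    def preferred_labels(self) -> frozenset[str]:
        return frozenset(self._preferred)

    def __len__(self) -> int:
        return len(self._alias)


@dataclass(frozen=True)
class NormalizationConfig:
    """Knobs of the normalization rule pipeline.

    ``species_prefixes`` are short genus-species codes stripped from gene
    names when the remainder is known (St = *Solanum tuberosum*,
    Le = *Lycopersicon esculentum*, Sl = *Solanum lycopersicum*,
    Ca = *Capsicum annuum*, At = *Arabidopsis thaliana*,
    Nt = *Nicotiana tabacum*).  ``rule_order`` must be a permutation of
    :data:`RULE_NAMES`.
    """

    species_prefixes: tuple[str, ...] = ("St", "Le", "Sl", "Ca", "At", "Nt")
    ec_map: Mapping[str, str] = field(default_factory=dict)
    spelling_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPELLING_MAP)
    )
    greek_map: Mapping[str, str] = field(default_factory=lambda: dict(GREEK_MAP))
    strip_family_digits: bool = True
    rule_order: tuple[str, ...] = RULE_NAMES

    def __post_init__(self) -> None:
        if sorted(self.rule_order) != sorted(RULE_NAMES):
            raise ValueError(
                f"rule_order must be a permutation of {RULE_NAMES}, "
                f"got {self.rule_order}"
            )

    @classmethod
    def with_ec_map_tsv(cls, path: str | Path, **kwargs) -> "NormalizationConfig":
        """Build a config whose EC map is read from ``ec<TAB>enzyme`` rows."""
        ec_map = {}
        with open(path, newline="", encoding="utf-8") as handle:
            for row in csv.reader(handle, delimiter="\t"):
                if len(row) >= 2 and not row[0].startswith("#"):
                    ec_map[row[0].strip()] = row[1].strip()
        return cls(ec_map=ec_map, **kwargs)


def _rule_greek_spelling(label: str, config: NormalizationConfig) -> str:
    out = "".join(config.greek_map.get(ch, ch) for ch in label)
    spelling = config.spelling_map
    if spelling:
        out = _WORD_RE.sub(
            lambda m: spelling.get(m.group(0).lower(), m.group(0)), out
        )
    return out


def _rule_strip_marks(label: str, config: NormalizationConfig) -> str:
    return "".join(ch for ch in label if ch not in _MARKS)


def _rule_uppercase(label: str, config: NormalizationConfig) -> str:
    return label.upper()


def _known(label: str, table: SynonymTable, known: frozenset[str]) -> bool:
    return table.resolves(label) or label.upper() in known


def _rule_species_prefix(
    label: str,
    config: NormalizationConfig,
    table: SynonymTable,
    known: frozenset[str],
) -> str:
    for prefix in config.species_prefixes:
        p = prefix.upper()
        if label.upper().startswith(p) and len(label) > len(p):
            remainder = label[len(p):]
            if _known(remainder, table, known):
                return remainder
    return label


def _rule_family_suffix(
    label: str,
    config: NormalizationConfig,
    table: SynonymTable,
    known: frozenset[str],
) -> str:
    if not config.strip_family_digits:
        return label
    match = _FAMILY_SUFFIX_RE.match(label)
    if match:
        base = match.group(1)
        if _known(base, table, known):
            return base
    return label


def _rule_ec_lookup(
    label: str, config: NormalizationConfig
) -> str:
    match = _EC_RE.match(label.strip())
    if match:
        name = config.ec_map.get(match.group(1))
        if name is not None:
            return name.upper()
    return label


def normalize_label(
    raw: str,
    table: SynonymTable,
    config: Optional[NormalizationConfig] = None,
    known: Iterable[str] = (),
) -> str:
    """Map a raw surface form to its canonical preferred label.

    ``known`` is an optional extra set of resolvable labels (typically the
    preferred labels of the active lexicon) consulted by the prefix/suffix
    stripping guards alongside the synonym table.
    """
    if not raw:
        raise ValueError("cannot normalize an empty label")
    if config is None:
        config = NormalizationConfig()
    known_set = frozenset(k.upper() for k in known)
    label = raw.strip()
    for rule in config.rule_order:
        if rule == "greek_spelling":
            label = _rule_greek_spelling(label, config)
        elif rule == "strip_marks":
            label = _rule_strip_marks(label, config)
        elif rule == "uppercase":
            label = _rule_uppercase(label, config)
        elif rule == "species_prefix":
            label = _rule_species_prefix(label, config, table, known_set)
        elif rule == "family_suffix":
            label = _rule_family_suffix(label, config, table, known_set)
        elif rule == "ec_lookup":
            label = _rule_ec_lookup(label, config)
    if not label:
        # input had no content beyond removable marks; leave it recognizable
        return raw.strip().upper()
    preferred = table.lookup(label)
    if preferred is not None:
        return preferred
    if not table.resolves(label) and label.upper() not in known_set:
        logger.debug("unresolved label %r (processed form %r)", raw, label)
    return label.upper()


def is_normalized(
    label: str,
    table: SynonymTable,
    config: Optional[NormalizationConfig] = None,
    known: Iterable[str] = (),
) -> bool:
    """True iff ``label`` is a fixed point of :func:`normalize_label`."""
    return normalize_label(label, table, config, known) == label


@dataclass(frozen=True)
class Normalizer:
    """Callable bundle of a synonym table, a config and extra known labels."""

    table: SynonymTable
    config: NormalizationConfig = field(default_factory=NormalizationConfig)
    known: frozenset[str] = frozenset()

    def __call__(self, raw: str) -> str:
        return normalize_label(raw, self.table, self.config, self.known)

    def is_normalized(self, label: str) -> bool:
        return self(label) == label
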