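"""Core domain types for combinatorial mutant deconvolutions.

A *deconvolution* of an n-fold mutant is the set of all 2^n intermediate
genotypes between a parent enzyme and the full variant, each measured for one
or more traits.  Genotypes are written in the compact dash notation used for
the P450 BM3 R47I/T49I/Y51I series: ``---`` is the parent, ``I--`` carries
only the first mutation, ``III`` carries all three.  A ``-`` means the
mutation at that position is absent; any other single character means it is
present (conventionally the introduced residue letter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Genotype",
    "TraitDefinition",
    "Measurement",
    "DeconvolutionDataset",
    "ValidationReport",
    "GenotypeFormatError",
    "DatasetError",
    "parse_genotype",
    "format_genotype",
    "validate_dataset",
]

STANDARD_TEMPERATURE = 298.15  # kelvin; assays run at 25 degC unless stated


class GenotypeFormatError(ValueError):
    """Raised when a genotype label cannot be parsed."""


class DatasetError(ValueError):
    """Raised for structurally invalid datasets (e.g. missing parent)."""


@dataclass(frozen=True)
class Genotype:
    """Presence/absence vector over an ordered list of mutation sites.

    Parameters
    ----------
    sites : tuple of str
        Ordered site labels, e.g. ``("R47I", "T49I", "Y51I")``.
    present : tuple of bool
        Whether the mutation at each site is present.
    """

    sites: tuple[str, ...]
    present: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.present):
            raise ValueError(
                f"{len(self.sites)} sites but {len(self.present)} presence flags"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def indices(self) -> frozenset[int]:
        """Indices of present mutations."""
        return frozenset(i for i, p in enumerate(self.present) if p)

    @property
    def n_mutations(self) -> int:
        return sum(self.present)

    @property
    def is_parent(self) -> bool:
        return not any(self.present)

    @property
    def label(self) -> str:
        return format_genotype(self)

    @classmethod
    def from_indices(cls, sites: Sequence[str], indices: Iterable[int]) -> "Genotype":
        idx = set(indices)
        return cls(tuple(sites), tuple(i in idx for i in range(len(sites))))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _presence_mark(site_label: str) -> str:
    """Single-character mark for a present mutation.

    Site labels in the ``R47I`` style end with the introduced residue; that
    letter is the conventional mark (hence ``I--`` for R47I alone).  Labels
    not in that style fall back to ``+``.
    """
    if site_label and site_label[-1].isalpha():
        return site_label[-1].upper()
    return "+"


def parse_genotype(label: str, sites: Sequence[str], *, strict: bool = False) -> Genotype:
    """Parse a dash-notation label into a :class:`Genotype`.

    Position ``i`` is present iff character ``i`` is not ``-``.  With
    ``strict=True`` the presence mark must equal the site's conventional
    mark (the introduced residue letter).

    >>> parse_genotype("-I-", ["R47I", "T49I", "Y51I"]).present
    (False, True, False)
    """
    sites = tuple(sites)
    if len(label) != len(sites):
        raise GenotypeFormatError(
            f"label {label!r} has length {len(label)}, expected {len(sites)}"
        )
    present = []
    for i, ch in enumerate(label):
        if ch == "-":
            present.append(False)
        else:
            if strict and ch != _presence_mark(sites[i]):
                raise GenotypeFormatError(
                    f"label {label!r}: mark {ch!r} at position {i} does not match "
                    f"site {sites[i]!r} (expected {_presence_mark(sites[i])!r})"
                )
            present.append(True)
    return Genotype(sites, tuple(present))


def format_genotype(genotype: Genotype) -> str:
    """Render a genotype back to dash notation (inverse of :func:`parse_genotype`)."""
    return "".join(
        _presence_mark(s) if p else "-"
        for s, p in zip(genotype.sites, genotype.present)
    )


@dataclass(frozen=True)
class TraitDefinition:
    """Metadata for one trait.

    Attributes
    ----------
    name : str
        Unique identifier within a dataset (e.g. ``"ttf"``).
    units : str
        Free-text units (``"%"``, ``"kJ/mol"``, ``"min^-1"``, ``""``).
    higher_is_better : bool
        Orientation used when classifying effects as beneficial/deleterious
        and when scanning pathways for local minima.
    kind : str
        ``"measured"`` or ``"derived"``.
    inputs : tuple of str
        For derived traits, the traits it is computed from.
    precision : int
        Decimal places used in rendered report tables.
    """

    name: str
    units: str = ""
    higher_is_better: bool = True
    kind: str = "measured"
    inputs: tuple[str, ...] = ()
    precision: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("measured", "derived"):
            raise ValueError(f"kind must be 'measured' or 'derived', got {self.kind!r}")
        if self.kind == "derived" and not isinstance(self.inputs, tuple):
            object.__setattr__(self, "inputs", tuple(self.inputs))


@dataclass(frozen=True)
class Measurement:
    """Replicate measurements of one trait on one genotype.

    ``sem`` is the standard error of the mean, ``sd / sqrt(n)`` with the
    sample (n-1) standard deviation.  Measurements may carry raw replicates
    or only summary statistics (mean, sem, n).
    """

    genotype: Genotype
    trait: str
    mean: float
    sem: float
    n: int
    replicates: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError(f"sem must be >= 0, got {self.sem}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.replicates is not None and len(self.replicates) != self.n:
            raise ValueError(
                f"n={self.n} but {len(self.replicates)} replicates given"
            )

    @classmethod
    def from_replicates(
        cls, genotype: Genotype, trait: str, values: Sequence[float]
    ) -> "Measurement":
        values = tuple(float(v) for v in values)
        if not values:
            raise ValueError("at least one replicate required")
        n = len(values)
        mean = sum(values) / n
        if n > 1:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            sem = sd / math.sqrt(n)
        else:
            sem = 0.0
        return cls(genotype, trait, mean, sem, n, values)


def _canonical_key(genotype: Genotype) -> tuple:
    return (genotype.n_mutations, tuple(sorted(genotype.indices)))


@dataclass
class DeconvolutionDataset:
    """Genotype x trait table of replicate measurements for one deconvolution.

    The canonical genotype order is by number of mutations, then by site
    position (``---, I--, -I-, --I, II-, I-I, -II, III`` for n=3).
    """

    sites: tuple[str, ...]
    temperature: float = STANDARD_TEMPERATURE
    traits: dict[str, TraitDefinition] = field(default_factory=dict)
    _measurements: dict[tuple[str, str], Measurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)

    # -- construction -----------------------------------------------------

    @property
    def parent(self) -> Genotype:
        return Genotype(self.sites, (False,) * len(self.sites))

    def define_trait(self, definition: TraitDefinition) -> None:
        if definition.name in self.traits:
            raise DatasetError(f"trait {definition.name!r} already defined")
        self.traits[definition.name] = definition

    def add(self, measurement: Measurement, *, replace_existing: bool = False) -> None:
        key = (measurement.genotype.label, measurement.trait)
        if key in self._measurements and not replace_existing:
            raise DatasetError(f"duplicate measurement for {key}")
        if measurement.trait not in self.traits:
            self.traits[measurement.trait] = TraitDefinition(measurement.trait)
        self._measurements[key] = measurement

    # -- lookup -----------------------------------------------------------

    def _label_of(self, genotype: Genotype | str) -> str:
        return genotype if isinstance(genotype, str) else genotype.label

    def has(self, genotype: Genotype | str, trait: str) -> bool:
        return (self._label_of(genotype), trait) in self._measurements

    def get(self, genotype: Genotype | str, trait: str) -> Measurement:
        key = (self._label_of(genotype), trait)
        try:
            return self._measurements[key]
        except KeyError:
            raise KeyError(f"no measurement for genotype {key[0]!r}, trait {key[1]!r}")

    def value(self, genotype: Genotype | str, trait: str) -> float:
        return self.get(genotype, trait).mean

    def sem(self, genotype: Genotype | str, trait: str) -> float:
        return self.get(genotype, trait).sem

    def genotype_from_indices(self, indices: Iterable[int]) -> Genotype:
        return Genotype.from_indices(self.sites, indices)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    def genotypes(self, trait: str | None = None) -> list[Genotype]:
        """Measured genotypes in canonical order (optionally for one trait)."""
        seen: dict[str, Genotype] = {}
        for (label, t), m in self._measurements.items():
            if trait is None or t == trait:
                seen.setdefault(label, m.genotype)
        return sorted(seen.values(), key=_canonical_key)

    def measurements(self) -> list[Measurement]:
        return [
            self._measurements[key]
            for key in sorted(
                self._measurements,
                key=lambda k: (_canonical_key(self._measurements[k].genotype), k[1]),
            )
        ]

    # -- completeness -----------------------------------------------------

    def all_genotypes(self) -> list[Genotype]:
        """All 2^n presence vectors in canonical order."""
        out = []
        for mask in range(2 ** self.n_sites):
            out.append(
                Genotype(
                    self.sites,
                    tuple(bool(mask >> i & 1) for i in range(self.n_sites)),
                )
            )
        return sorted(out, key=_canonical_key)

    def missing(self, trait: str) -> list[str]:
        """Labels of the 2^n genotypes lacking a measurement for ``trait``."""
        return [
            g.label for g in self.all_genotypes() if not self.has(g, trait)
        ]

    def is_complete(self, trait: str | None = None) -> bool:
        traits = [trait] if trait is not None else self.trait_names
        return all(not self.missing(t) for t in traits)


@dataclass
class ValidationReport:
    """Report-only result of :func:`validate_dataset`."""

    n_genotypes: int
    n_traits: int
    complete: bool
    missing: dict[str, list[str]]
    warnings: list[str]
    errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        status = "complete" if self.complete else "incomplete"
        lines = [f"{status}, {self.n_genotypes} genotypes, {self.n_traits} traits"]
        for trait, miss in self.missing.items():
            if miss:
                lines.append(f"  missing for {trait}: {', '.join(miss)}")
        lines.extend(f"  warning: {w}" for w in self.warnings)
        lines.extend(f"  error: {e}" for e in self.errors)
        return "\n".join(lines)


def validate_dataset(
    dataset: DeconvolutionDataset,
    *,
    sem_rtol: float = 1e-6,
    consistency_rtol: float = 0.02,
) -> ValidationReport:
    """Check completeness, SEM consistency and derived-trait identities.

    The derived-trait check currently covers the product-formation identity
    PFR = NCR x CE (with CE in percent or as a fraction) wherever all three
    traits are present for a genotype.
    """
    warnings: list[str] = []
    errors: list[str] = []
    if not dataset._measurements:
        errors.append("no measurements")
        return ValidationReport(0, 0, False, {}, warnings, errors)

    missing = {t: dataset.missing(t) for t in dataset.trait_names}
    complete = all(not m for m in missing.values())

    ns_per_trait: dict[str, set[int]] = {}
    for m in dataset.measurements():
        ns_per_trait.setdefault(m.trait, set()).add(m.n)
        if m.replicates is not None and m.n > 1:
            recomputed = Measurement.from_replicates(m.genotype, m.trait, m.replicates)
            scale = max(abs(m.sem), abs(recomputed.sem), 1e-12)
            if abs(m.sem - recomputed.sem) > sem_rtol * scale:
                warnings.append(
                    f"SEM for {m.genotype.label}/{m.trait} ({m.sem:g}) does not match "
                    f"replicates ({recomputed.sem:g})"
                )
    for trait, ns in ns_per_trait.items():
        if len(ns) > 1:
            warnings.append(f"inconsistent replicate counts for {trait}: {sorted(ns)}")

    names = set(dataset.trait_names)
    if {"pfr", "ncr", "ce"} <= names:
        units = dataset.traits["ce"].units
        # undeclared units: accept the percent or the fraction convention
        divisors = (100.0,) if "%" in units else (1.0, 100.0) if not units else (1.0,)
        for g in dataset.genotypes():
            if all(dataset.has(g, t) for t in ("pfr", "ncr", "ce")):
                observed = dataset.value(g, "pfr")
                candidates = [
                    dataset.value(g, "ncr") * dataset.value(g, "ce") / d
                    for d in divisors
                ]
                ok = any(
                    abs(c - observed) <= consistency_rtol * max(abs(c), abs(observed), 1e-12)
                    for c in candidates
                )
                if not ok:
                    warnings.append(
                        f"PFR inconsistency for {g.label}: pfr={observed:g} but "
                        f"ncr*ce={candidates[0]:g}"
                    )

    n_genotypes = len(dataset.genotypes())
    return ValidationReport(
        n_genotypes, len(dataset.trait_names), complete, missing, warnings, errors
    )
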