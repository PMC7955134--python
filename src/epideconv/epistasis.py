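"""Additive expectations, epistasis magnitudes and the interaction taxonomy.

For a trait f measured on every genotype, the effect of a mutation set A
relative to the parent is w(A) = f(A) - f(parent).  A *combination split*
partitions the mutations of a genotype U into k >= 2 disjoint parts
A_1..A_k; under additivity

    expected(U) = f(parent) + sum_i w(A_i)

and the epistasis magnitude is the deviation of the measured value

    epsilon = f(U) - expected(U)

on the trait's own scale.  SEMs propagate as independent errors:
SEM(expected)^2 = sum_i sem(A_i)^2 + (k-1)^2 sem(parent)^2 and
sem(epsilon)^2 = sem(U)^2 + SEM(expected)^2.

Each interaction is classified by the signs of the oriented part effects,
epsilon, and the combined effect:

* ADD  — |epsilon| within threshold of zero (no epistasis);
* ME   — all parts share one effect sign; the combination over- (+) or
         under-shoots (-) additivity without reversing that sign;
* RSE  — all parts share one sign but the combined effect has the opposite
         sign (+RSE: deleterious parts, beneficial combination; -RSE: the
         reverse);
* SE   — parts have mixed effect signs; positive or negative by the sign of
         epsilon.

"Beneficial" follows each trait's declared orientation (higher- or
lower-is-better).  Part effects within threshold of zero are sign ties; they
are grouped with the majority sign (favouring ME over SE) and flagged
``marginal`` in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .datamodel import DeconvolutionDataset, Genotype

__all__ = [
    "Thresholds",
    "CombinationSplit",
    "EpistasisResult",
    "EpistasisTable",
    "LABELS",
    "enumerate_splits",
    "additive_expectation",
    "epistasis_epsilon",
    "classify_epistasis",
    "analyze_all",
    "summarize_types",
]

LABELS = ("+ME", "-ME", "+SE", "-SE", "+RSE", "-RSE", "ADD")


@dataclass(frozen=True)
class Thresholds:
    """Significance rule separating real effects from replicate noise.

    An effect x with standard error s counts as zero when
    |x| <= max(k_sig * s, abs_tol).  The defaults (k_sig=1, abs_tol=0)
    treat one standard error as the resolution limit of n=2 assays.
    """

    k_sig: float = 1.0
    abs_tol: float = 0.0

    def tol(self, sem: float) -> float:
        return max(self.k_sig * sem, self.abs_tol)

    def sign(self, value: float, sem: float) -> int:
        """-1, 0 (within threshold) or +1."""
        t = self.tol(sem)
        if value > t:
            return 1
        if value < -t:
            return -1
        return 0


@dataclass(frozen=True)
class CombinationSplit:
    """A partition of a target genotype's mutations into disjoint parts."""

    parts: tuple[frozenset[int], ...]

    def __post_init__(self) -> None:
        if len(self.parts) < 2:
            raise ValueError("a split needs at least 2 parts")
        if any(not p for p in self.parts):
            raise ValueError("parts must be nonempty")
        total = sum(len(p) for p in self.parts)
        if total != len(self.union):
            raise ValueError("parts must be pairwise disjoint")
        ordered = tuple(sorted(self.parts, key=lambda p: (len(p), sorted(p))))
        object.__setattr__(self, "parts", ordered)

    @property
    def union(self) -> frozenset[int]:
        return frozenset().union(*self.parts)

    @property
    def k(self) -> int:
        return len(self.parts)

    @property
    def kind(self) -> str:
        """Table shorthand: B for binary, T for the all-singles tertiary, else k-way."""
        if self.k == 2:
            return "B"
        if self.k == 3:
            return "T"
        return f"{self.k}-way"

    def part_genotypes(self, dataset: DeconvolutionDataset) -> list[Genotype]:
        return [dataset.genotype_from_indices(p) for p in self.parts]

    def union_genotype(self, dataset: DeconvolutionDataset) -> Genotype:
        return dataset.genotype_from_indices(self.union)

    def describe(self, dataset: DeconvolutionDataset) -> str:
        parts = " + ".join(g.label for g in self.part_genotypes(dataset))
        return f"{parts} -> {self.union_genotype(dataset).label}"


def _partitions(indices: tuple[int, ...]) -> Iterable[list[list[int]]]:
    """All set partitions of ``indices`` (standard recursive construction)."""
    if not indices:
        yield []
        return
    first, rest = indices[0], indices[1:]
    for partial in _partitions(rest):
        for i in range(len(partial)):
            yield partial[:i] + [[first] + partial[i]] + partial[i + 1 :]
        yield [[first]] + partial


def enumerate_splits(n_sites: int, mode: str = "paper") -> list[CombinationSplit]:
    """Enumerate combination splits in deterministic canonical order.

    Modes
    -----
    ``paper``
        Every unordered binary split of every achievable sub-genotype with
        >= 2 mutations, plus the all-singles split of the full genotype.
        For n=3 this reproduces the canonical 7-row table (6 binary + 1
        tertiary).
    ``binary_only``
        Only the binary splits.
    ``all_kway``
        Every partition (>= 2 blocks) of every sub-genotype.

    Order: by union size, then union indices, then parts.
    """
    if n_sites < 2:
        raise ValueError(f"need at least 2 sites, got {n_sites}")
    if mode not in ("paper", "binary_only", "all_kway"):
        raise ValueError(f"unknown mode {mode!r}")

    splits: set[CombinationSplit] = set()
    all_indices = tuple(range(n_sites))
    for size in range(2, n_sites + 1):
        for union in combinations(all_indices, size):
            if mode == "all_kway":
                for partition in _partitions(union):
                    if len(partition) >= 2:
                        splits.add(
                            CombinationSplit(tuple(frozenset(b) for b in partition))
                        )
            else:
                uset = set(union)
                for asize in range(1, size // 2 + 1):
                    for a in combinations(union, asize):
                        b = frozenset(uset - set(a))
                        if len(a) == len(b) and tuple(sorted(a)) > tuple(sorted(b)):
                            continue  # unordered pair: keep one orientation
                        splits.add(CombinationSplit((frozenset(a), b)))
    if mode == "paper":
        splits.add(
            CombinationSplit(tuple(frozenset([i]) for i in all_indices))
        )

    return sorted(
        splits,
        key=lambda s: (
            len(s.union),
            tuple(sorted(s.union)),
            len(s.parts),
            tuple(tuple(sorted(p)) for p in s.parts),
        ),
    )


@dataclass
class EpistasisResult:
    """Epistasis of one combination split on one trait."""

    split: CombinationSplit
    trait: str
    combination: str  # e.g. "I-- + -I- + --I -> III"
    resulting_genotype: str
    w_parts: tuple[float, ...]
    sem_w_parts: tuple[float, ...]
    w_combined: float
    sem_w_combined: float
    expected: float
    sem_expected: float
    observed: float
    sem_observed: float
    epsilon: float
    sem_epsilon: float
    label: str | None = None
    significant: bool | None = None
    marginal_parts: tuple[int, ...] = ()

    def cell(self, precision: int = 1) -> str:
        """Report-table cell in the ``+SE 9.0`` / ``ADD -0.2`` style."""
        label = self.label or "?"
        return f"{label} {self.epsilon:.{precision}f}"


def additive_expectation(
    dataset: DeconvolutionDataset,
    parts: Sequence[frozenset[int] | Iterable[int]],
    trait: str,
) -> tuple[float, float]:
    """Expected trait value of the union of ``parts`` under additivity.

    Returns ``(expected, sem)`` with
    expected = f(parent) + sum_i (f(part_i) - f(parent)) and
    sem^2 = sum_i sem_i^2 + (k-1)^2 sem_parent^2 (the parent mean enters the
    expectation k-1 times).
    """
    parts = [frozenset(p) for p in parts]
    parent = dataset.parent
    f_parent = dataset.value(parent, trait)
    sem_parent = dataset.sem(parent, trait)
    expected = f_parent
    var = (len(parts) - 1) ** 2 * sem_parent**2
    for p in parts:
        g = dataset.genotype_from_indices(p)
        expected += dataset.value(g, trait) - f_parent
        var += dataset.sem(g, trait) ** 2
    return expected, math.sqrt(var)


def epistasis_epsilon(
    dataset: DeconvolutionDataset,
    split: CombinationSplit,
    trait: str,
) -> EpistasisResult:
    """Epsilon = observed - additive expectation for one split (unclassified).

    Raises ``KeyError`` if any required genotype lacks a measurement for
    ``trait`` (callers enumerate and skip).
    """
    parent = dataset.parent
    f_parent = dataset.value(parent, trait)
    sem_parent = dataset.sem(parent, trait)

    w_parts, sem_w_parts = [], []
    for g in split.part_genotypes(dataset):
        w_parts.append(dataset.value(g, trait) - f_parent)
        sem_w_parts.append(math.hypot(dataset.sem(g, trait), sem_parent))

    union = split.union_genotype(dataset)
    observed = dataset.value(union, trait)
    sem_observed = dataset.sem(union, trait)
    expected, sem_expected = additive_expectation(dataset, split.parts, trait)
    epsilon = observed - expected
    sem_epsilon = math.hypot(sem_observed, sem_expected)

    return EpistasisResult(
        split=split,
        trait=trait,
        combination=split.describe(dataset),
        resulting_genotype=union.label,
        w_parts=tuple(w_parts),
        sem_w_parts=tuple(sem_w_parts),
        w_combined=observed - f_parent,
        sem_w_combined=math.hypot(sem_observed, sem_parent),
        expected=expected,
        sem_expected=sem_expected,
        observed=observed,
        sem_observed=sem_observed,
        epsilon=epsilon,
        sem_epsilon=sem_epsilon,
    )


def classify_epistasis(
    w_parts: Sequence[float],
    w_combined: float,
    epsilon: float,
    sem_epsilon: float,
    *,
    sem_w_parts: Sequence[float] | None = None,
    sem_w_combined: float = 0.0,
    thresholds: Thresholds = Thresholds(),
    higher_is_better: bool = True,
) -> tuple[str, tuple[int, ...]]:
    """Assign one of ``+ME, -ME, +SE, -SE, +RSE, -RSE, ADD``.

    Returns ``(label, marginal_part_indices)`` where the second element lists
    parts whose effect sign was a tie (within threshold of zero) and was
    resolved by the majority-sign rule.  All sign logic runs on the oriented
    scale, so a decrease of a lower-is-better trait is beneficial.
    """
    if sem_w_parts is None:
        sem_w_parts = [0.0] * len(w_parts)
    orient = 1.0 if higher_is_better else -1.0
    eo = orient * epsilon
    wo = [orient * w for w in w_parts]
    wco = orient * w_combined

    if abs(eo) <= thresholds.tol(sem_epsilon):
        return "ADD", ()

    signs = [thresholds.sign(w, s) for w, s in zip(wo, sem_w_parts)]
    marginal = tuple(i for i, s in enumerate(signs) if s == 0)
    decided = [s for s in signs if s != 0]
    if decided:
        majority = 1 if sum(decided) >= 0 else -1
    else:
        # every part is a tie: fall back to the combined effect, then epsilon
        wc_sign = thresholds.sign(wco, sem_w_combined)
        majority = wc_sign if wc_sign != 0 else (1 if eo > 0 else -1)
    resolved = [s if s != 0 else majority for s in signs]

    eps_sign = "+" if eo > 0 else "-"
    if len(set(resolved)) > 1:
        return f"{eps_sign}SE", marginal

    shared = resolved[0]
    wc_sign = thresholds.sign(wco, sem_w_combined)
    if wc_sign != 0 and wc_sign == -shared:
        return ("+RSE" if shared < 0 else "-RSE"), marginal
    return f"{eps_sign}ME", marginal


@dataclass
class EpistasisTable:
    """All epistasis results for one dataset, plus skips and summaries."""

    results: list[EpistasisResult]
    skipped: list[tuple[str, str, str]]  # (combination, trait, reason)
    thresholds: Thresholds
    mode: str
    traits: list[str] = field(default_factory=list)

    def for_trait(self, trait: str) -> list[EpistasisResult]:
        return [r for r in self.results if r.trait == trait]

    def summaries(self) -> dict[str, dict]:
        return {t: summarize_types(self.for_trait(t)) for t in self.traits}


def analyze_all(
    dataset: DeconvolutionDataset,
    traits: Sequence[str] | None = None,
    mode: str = "paper",
    thresholds: Thresholds = Thresholds(),
) -> EpistasisTable:
    """Epistasis magnitude and class for every (split, trait) combination.

    Splits whose part or union genotypes are unmeasured for a trait are
    skipped and listed with a reason.  Results come back in the deterministic
    split order of :func:`enumerate_splits`, traits in dataset order.
    """
    trait_names = list(traits) if traits is not None else dataset.trait_names
    unknown = [t for t in trait_names if t not in dataset.traits]
    if unknown:
        raise KeyError(f"unknown trait(s): {unknown}")

    splits = enumerate_splits(dataset.n_sites, mode=mode)
    results: list[EpistasisResult] = []
    skipped: list[tuple[str, str, str]] = []
    for split in splits:
        for trait in trait_names:
            needed = split.part_genotypes(dataset) + [
                split.union_genotype(dataset),
                dataset.parent,
            ]
            missing = [g.label for g in needed if not dataset.has(g, trait)]
            if missing:
                skipped.append(
                    (split.describe(dataset), trait, f"unmeasured: {', '.join(missing)}")
                )
                continue
            result = epistasis_epsilon(dataset, split, trait)
            definition = dataset.traits[trait]
            label, marginal = classify_epistasis(
                result.w_parts,
                result.w_combined,
                result.epsilon,
                result.sem_epsilon,
                sem_w_parts=result.sem_w_parts,
                sem_w_combined=result.sem_w_combined,
                thresholds=thresholds,
                higher_is_better=definition.higher_is_better,
            )
            result.label = label
            result.significant = label != "ADD"
            result.marginal_parts = marginal
            results.append(result)
    return EpistasisTable(results, skipped, thresholds, mode, trait_names)


def summarize_types(results: Sequence[EpistasisResult]) -> dict:
    """Counts and integer percentages per label, class and sign."""
    if not results:
        raise ValueError("no results to summarize")
    total = len(results)
    labels = [r.label for r in results]
    by_label = {lab: labels.count(lab) for lab in LABELS if lab in labels}
    by_class: dict[str, int] = {}
    for lab in labels:
        by_class[lab.lstrip("+-")] = by_class.get(lab.lstrip("+-"), 0) + 1
    positive = sum(1 for lab in labels if lab.startswith("+"))
    negative = sum(1 for lab in labels if lab.startswith("-"))

    def pct(c: dict[str, int]) -> dict[str, int]:
        return {k: round(100 * v / total) for k, v in c.items()}

    return {
        "n": total,
        "counts": by_label,
        "percent": pct(by_label),
        "class_counts": by_class,
        "class_percent": pct(by_class),
        "sign_counts": {"positive": positive, "negative": negative},
        "sign_percent": {
            "positive": round(100 * positive / total),
            "negative": round(100 * negative / total),
        },
    }
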