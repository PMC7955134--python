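"""Stepwise mutational pathways and multiparametric accessibility.

A pathway is one of the n! orderings in which the n mutations can be added
one at a time, i.e. a monotone chain of n+1 genotypes from the parent to the
full variant.  A step is *permitted* for a trait when the oriented change
f(to) - f(from) is not a decrease beyond tolerance; a pathway is *favoured*
(accessible) when every step is permitted for every considered trait, and
*disfavoured* otherwise — it passes through a local minimum and the first
blocking step is recorded.

The default tolerance for a step is one combined standard error,
sqrt(sem_from^2 + sem_to^2), so that ties and sub-noise dips do not block a
pathway; both the multiplier and an absolute floor are configurable.

Pathways are numbered 1..n! in lexicographic order of the site ordering.
For the three-site series (R47I, T49I, Y51I) this puts the two orderings
that introduce Y51I first at positions 5 and 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import pandas as pd

from .datamodel import DeconvolutionDataset, Genotype
from .epistasis import Thresholds

__all__ = [
    "Pathway",
    "StepRecord",
    "PathwayClassification",
    "enumerate_pathways",
    "evaluate_pathway",
    "classify_all",
    "landscape_grid",
]


@dataclass(frozen=True)
class Pathway:
    """One ordering of the n mutation sites."""

    ordering: tuple[int, ...]
    number: int  # 1-based position in lexicographic order

    @property
    def n_sites(self) -> int:
        return len(self.ordering)

    def genotype_sequence(self, sites: Sequence[str]) -> list[Genotype]:
        """Parent -> ... -> full variant (n+1 genotypes)."""
        seq = []
        acc: set[int] = set()
        seq.append(Genotype.from_indices(sites, acc))
        for i in self.ordering:
            acc.add(i)
            seq.append(Genotype.from_indices(sites, acc))
        return seq

    def describe(self, sites: Sequence[str]) -> str:
        steps = " -> ".join(g.label for g in self.genotype_sequence(sites))
        order = ", ".join(sites[i] for i in self.ordering)
        return f"pathway {self.number} ({order}): {steps}"


@dataclass(frozen=True)
class StepRecord:
    """One mutational step, with per-trait deltas and verdicts."""

    index: int  # 1-based step number
    from_label: str
    to_label: str
    deltas: dict[str, float]  # oriented: positive = improvement
    tolerances: dict[str, float]
    permitted: bool
    blocking_traits: tuple[str, ...]


@dataclass(frozen=True)
class PathwayClassification:
    pathway: Pathway
    traits: tuple[str, ...]
    steps: tuple[StepRecord, ...]
    evaluable: bool
    favoured: bool
    first_blocking_step: StepRecord | None
    reason: str = ""

    @property
    def verdict(self) -> str:
        if not self.evaluable:
            return "unevaluable"
        return "favoured" if self.favoured else "disfavoured"


def enumerate_pathways(n_sites: int) -> list[Pathway]:
    """All n! site orderings, numbered in lexicographic order."""
    if n_sites < 1:
        raise ValueError(f"need at least 1 site, got {n_sites}")
    return [
        Pathway(tuple(p), i + 1)
        for i, p in enumerate(permutations(range(n_sites)))
    ]


def evaluate_pathway(
    dataset: DeconvolutionDataset,
    pathway: Pathway,
    traits: Sequence[str],
    thresholds: Thresholds = Thresholds(),
) -> PathwayClassification:
    """Scan one pathway for local minima over the given traits."""
    traits = tuple(traits)
    unknown = [t for t in traits if t not in dataset.traits]
    if unknown:
        raise KeyError(f"unknown trait(s): {unknown}")
    sequence = pathway.genotype_sequence(dataset.sites)

    missing = [
        (g.label, t)
        for g in sequence
        for t in traits
        if not dataset.has(g, t)
    ]
    if missing:
        detail = ", ".join(f"{g}/{t}" for g, t in missing)
        return PathwayClassification(
            pathway, traits, (), False, False, None, f"unmeasured: {detail}"
        )

    steps: list[StepRecord] = []
    first_block: StepRecord | None = None
    for idx in range(1, len(sequence)):
        g_from, g_to = sequence[idx - 1], sequence[idx]
        deltas: dict[str, float] = {}
        tols: dict[str, float] = {}
        blocking: list[str] = []
        for trait in traits:
            orient = 1.0 if dataset.traits[trait].higher_is_better else -1.0
            delta = orient * (dataset.value(g_to, trait) - dataset.value(g_from, trait))
            tol = thresholds.tol(
                math.hypot(dataset.sem(g_from, trait), dataset.sem(g_to, trait))
            )
            deltas[trait] = delta
            tols[trait] = tol
            if delta < -tol:
                blocking.append(trait)
        record = StepRecord(
            idx, g_from.label, g_to.label, deltas, tols, not blocking, tuple(blocking)
        )
        steps.append(record)
        if blocking and first_block is None:
            first_block = record

    return PathwayClassification(
        pathway,
        traits,
        tuple(steps),
        True,
        first_block is None,
        first_block,
    )


def classify_all(
    dataset: DeconvolutionDataset,
    traits: Sequence[str],
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[PathwayClassification], dict]:
    """Verdicts for all n! pathways plus an accessibility summary."""
    classifications = [
        evaluate_pathway(dataset, p, traits, thresholds)
        for p in enumerate_pathways(dataset.n_sites)
    ]
    favoured = [c for c in classifications if c.evaluable and c.favoured]
    summary = {
        "total": len(classifications),
        "evaluable": sum(1 for c in classifications if c.evaluable),
        "accessible": len(favoured),
        "accessible_pathways": [c.pathway.number for c in favoured],
        "first_mutations": sorted(
            {dataset.sites[c.pathway.ordering[0]] for c in favoured}
        ),
        "traits": list(traits),
    }
    return classifications, summary


def landscape_grid(
    dataset: DeconvolutionDataset,
    traits: Sequence[str],
) -> pd.DataFrame:
    """Long-format fitness-pathway-landscape grid for external plotting.

    One row per (pathway, step, trait): columns ``pathway``, ``step`` (0..n,
    0 = parent), ``genotype``, ``trait``, ``value``, ``sem``.  Values are the
    dataset means, untransformed.
    """
    rows = []
    for pathway in enumerate_pathways(dataset.n_sites):
        for step, genotype in enumerate(pathway.genotype_sequence(dataset.sites)):
            for trait in traits:
                if not dataset.has(genotype, trait):
                    continue
                rows.append(
                    {
                        "pathway": pathway.number,
                        "step": step,
                        "genotype": genotype.label,
                        "trait": trait,
                        "value": dataset.value(genotype, trait),
                        "sem": dataset.sem(genotype, trait),
                    }
                )
    return pd.DataFrame(rows, columns=["pathway", "step", "genotype", "trait", "value", "sem"])


def landscape_heatmap(grid: pd.DataFrame, trait: str, ax=None):
    """Pathway x step heat map of one trait from a :func:`landscape_grid` frame.

    Value-faithful cells (no interpolated surface); returns the matplotlib
    Axes.  Requires matplotlib, which is imported lazily.
    """
    import matplotlib.pyplot as plt

    sub = grid[grid.trait == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in grid")
    pivot = sub.pivot_table(index="pathway", columns="step", values="value")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * pivot.shape[1] + 2, 0.5 * pivot.shape[0] + 1.5))
    image = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="Blues")
    ax.set_xticks(range(pivot.shape[1]), [str(s) for s in pivot.columns])
    ax.set_yticks(range(pivot.shape[0]), [f"pathway {p}" for p in pivot.index])
    ax.set_xlabel("evolutionary step")
    ax.set_title(trait)
    ax.figure.colorbar(image, ax=ax, label=trait)
    return ax
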