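"""Synthetic deconvolution landscapes and the frozen reference fixture.

The generator realizes the additive-plus-interaction model that the
epistasis analysis inverts: for a genotype g (a set of present mutations)

    f(g) = parent + sum_{i in g} a_i + sum_{S subseteq g, |S| >= 2} eps_S

with i.i.d. normal replicate noise per genotype and trait.  Zero-noise data
therefore have exactly recoverable interaction coefficients, which anchors
the parameter-recovery tests.

:func:`bm3_fixture` loads the packaged eight-genotype P450 BM3
R47I/T49I/Y51I deconvolution dataset.  Its values are frozen constants,
assembled from published whole-cell characterization of that series: each
value is tagged ``reported`` (stated directly), ``solved`` (recovered by
inverting published epistasis identities), ``derived`` (computed from other
fixture traits) or ``assumed`` (a documented free choice consistent with
every published constraint).  Assumed values are synthetic stand-ins, not
measurements; see the provenance sidecar shipped next to the CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .datamodel import (
    DeconvolutionDataset,
    Measurement,
    STANDARD_TEMPERATURE,
    TraitDefinition,
)

__all__ = [
    "TraitLandscape",
    "LandscapeSpec",
    "generate_dataset",
    "load_landscape_spec",
    "example_landscape_spec",
    "bm3_fixture",
    "FIXTURE_CSV",
    "FIXTURE_SIDECAR",
]

FIXTURE_CSV = "bm3_deconvolution.csv"
FIXTURE_SIDECAR = "bm3_deconvolution.yaml"


@dataclass(frozen=True)
class TraitLandscape:
    """Ground-truth landscape for one trait.

    ``additive`` holds one effect per site (relative to parent);
    ``interactions`` maps site-index subsets of size >= 2 to injected
    epistasis coefficients.  ``noise_sd`` is the replicate standard
    deviation (0 for noise-free data).
    """

    parent_value: float
    additive: tuple[float, ...]
    interactions: Mapping[frozenset[int], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    units: str = ""
    higher_is_better: bool = True
    precision: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for subset in self.interactions:
            if len(subset) < 2:
                raise ValueError("interaction subsets need >= 2 sites")
            if any(i >= len(self.additive) or i < 0 for i in subset):
                raise ValueError(f"interaction subset {sorted(subset)} out of range")

    def model_value(self, present: frozenset[int]) -> float:
        value = self.parent_value + sum(self.additive[i] for i in present)
        for subset, coeff in self.interactions.items():
            if subset <= present:
                value += coeff
        return value


@dataclass(frozen=True)
class LandscapeSpec:
    """Full specification of a synthetic deconvolution dataset."""

    sites: tuple[str, ...]
    traits: Mapping[str, TraitLandscape]
    n_replicates: int = 2
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        for name, trait in self.traits.items():
            if len(trait.additive) != len(self.sites):
                raise ValueError(
                    f"trait {name!r}: {len(trait.additive)} additive effects for "
                    f"{len(self.sites)} sites"
                )


def generate_dataset(
    spec: LandscapeSpec,
    seed: int | np.random.Generator | None = 0,
) -> DeconvolutionDataset:
    """Draw a complete 2^n dataset from a landscape spec.

    Replicates are i.i.d. normal around the model value; a fixed seed gives a
    bit-identical dataset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dataset = DeconvolutionDataset(sites=spec.sites, temperature=spec.temperature)
    for name, trait in spec.traits.items():
        dataset.define_trait(
            TraitDefinition(
                name=name,
                units=trait.units,
                higher_is_better=trait.higher_is_better,
                precision=trait.precision,
            )
        )
    for genotype in dataset.all_genotypes():
        present = genotype.indices
        for name, trait in spec.traits.items():
            mean = trait.model_value(present)
            if trait.noise_sd > 0:
                values = mean + rng.normal(0.0, trait.noise_sd, size=spec.n_replicates)
            else:
                values = np.full(spec.n_replicates, mean)
            dataset.add(Measurement.from_replicates(genotype, name, values.tolist()))
    return dataset


# ---------------------------------------------------------------------------
# YAML landscape specs


def _parse_interactions(
    entries: Sequence[Mapping], sites: Sequence[str]
) -> dict[frozenset[int], float]:
    index = {s: i for i, s in enumerate(sites)}
    out: dict[frozenset[int], float] = {}
    for entry in entries or ():
        members = entry["sites"]
        idx = frozenset(
            index[m] if isinstance(m, str) else int(m) for m in members
        )
        out[idx] = float(entry["value"])
    return out


def load_landscape_spec(path) -> LandscapeSpec:
    """Read a :class:`LandscapeSpec` from YAML.

    Schema: ``sites`` (list), ``n_replicates``, ``temperature`` and a
    ``traits`` list of mappings with ``name``, ``parent_value``, ``additive``
    (one value per site), optional ``interactions`` (list of ``{sites,
    value}``), ``noise_sd``, ``units``, ``higher_is_better``, ``precision``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    sites = tuple(raw["sites"])
    if not raw.get("traits"):
        raise ValueError(f"{path}: landscape spec defines no traits")
    traits = {}
    for entry in raw["traits"]:
        traits[entry["name"]] = TraitLandscape(
            parent_value=float(entry["parent_value"]),
            additive=tuple(float(a) for a in entry["additive"]),
            interactions=_parse_interactions(entry.get("interactions"), sites),
            noise_sd=float(entry.get("noise_sd", 0.0)),
            units=entry.get("units", ""),
            higher_is_better=entry.get("higher_is_better", True),
            precision=int(entry.get("precision", 1)),
        )
    return LandscapeSpec(
        sites=sites,
        traits=traits,
        n_replicates=int(raw.get("n_replicates", 2)),
        temperature=float(raw.get("temperature", STANDARD_TEMPERATURE)),
    )


def example_landscape_spec() -> LandscapeSpec:
    """Small three-site example with one injected pairwise interaction."""
    return LandscapeSpec(
        sites=("A", "B", "C"),
        traits={
            "activity": TraitLandscape(
                parent_value=10.0,
                additive=(-4.0, 0.0, 10.0),
                interactions={frozenset({0, 1}): 51.0},
                noise_sd=1.0,
                units="min^-1",
            )
        },
        n_replicates=2,
    )


# ---------------------------------------------------------------------------
# the frozen reference fixture


def _fixture_text(name: str) -> str:
    return resources.files("epideconv.data").joinpath(name).read_text(encoding="utf-8")


def bm3_fixture(with_provenance: bool = False):
    """The frozen P450 BM3 R47I/T49I/Y51I deconvolution fixture.

    Eight genotypes (``---`` through ``III``) by seven traits (conv, ddg,
    ncr, pfr, ce, ttn, ttf), mean/SEM/n form with n=2 throughout.  With
    ``with_provenance=True`` also returns a dict mapping
    ``(genotype, trait)`` to the value's provenance tag plus the sidecar
    notes.
    """
    sidecar = yaml.safe_load(_fixture_text(FIXTURE_SIDECAR))
    sites = tuple(sidecar["sites"])
    dataset = DeconvolutionDataset(
        sites=sites, temperature=float(sidecar.get("temperature", STANDARD_TEMPERATURE))
    )
    for entry in sidecar["traits"]:
        dataset.define_trait(
            TraitDefinition(
                name=entry["name"],
                units=entry.get("units", ""),
                higher_is_better=entry.get("higher_is_better", True),
                kind=entry.get("kind", "measured"),
                inputs=tuple(entry.get("inputs", ())),
                precision=int(entry.get("precision", 1)),
            )
        )

    from .datamodel import parse_genotype  # local import to avoid cycle noise

    provenance: dict[tuple[str, str], str] = {}
    lines = _fixture_text(FIXTURE_CSV).strip().splitlines()
    header = lines[0].split(",")
    for line in lines[1:]:
        row = dict(zip(header, line.split(",")))
        genotype = parse_genotype(row["genotype"], sites)
        dataset.add(
            Measurement(
                genotype,
                row["trait"],
                float(row["mean"]),
                float(row["sem"]),
                int(row["n"]),
            )
        )
        provenance[(row["genotype"], row["trait"])] = row["provenance"]

    if with_provenance:
        return dataset, {"tags": provenance, "notes": sidecar.get("notes", "")}
    return dataset
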