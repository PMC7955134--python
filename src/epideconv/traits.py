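"""Derived kinetic traits and the selectivity -> ddG-dagger transform.

Traits measured for each deconvolution mutant include regioselectivity
(fraction of product flux to the target regioisomer), NADPH consumption rate
(NCR), coupling efficiency (CE), product formation rate (PFR = NCR x CE),
total turnover number (TTN) and total turnover frequency (TTF = TTN /
elapsed time).  Selectivity is mapped onto a free-energy scale via the
transition-state competition relation

    ddG = R*T*ln(p / (1 - p))   [kJ/mol]

where p is the fraction of flux to the target product: p = 0.5 gives 0, and
higher p (more selective) gives larger positive ddG.  Errors propagate either
by per-replicate recomputation (preferred, replicates exist) or by the delta
method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .datamodel import (
    DeconvolutionDataset,
    Measurement,
    STANDARD_TEMPERATURE,
    TraitDefinition,
)

__all__ = [
    "GAS_CONSTANT_KJ",
    "SelectivityValue",
    "DDG",
    "selectivity_to_ddg",
    "ddg_to_selectivity",
    "compute_pfr",
    "compute_ce",
    "compute_ttf",
    "correct_ncr",
    "augment_dataset",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1


@dataclass(frozen=True)
class SelectivityValue:
    """Fraction of product flux to the target regioisomer.

    ``basis`` records whether the fraction is relative to one competing
    product ("pairwise") or to all quantified products ("total", default).
    """

    p_target: float
    sem: float = 0.0
    basis: str = "total"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_target <= 1.0:
            raise ValueError(f"p_target must be in [0, 1], got {self.p_target}")
        if self.basis not in ("total", "pairwise"):
            raise ValueError(f"basis must be 'total' or 'pairwise', got {self.basis!r}")


@dataclass(frozen=True)
class DDG:
    """Relative transition-state free energy difference, kJ/mol."""

    value: float
    sem: float
    temperature: float


def selectivity_to_ddg(
    p: SelectivityValue | float,
    temperature: float = STANDARD_TEMPERATURE,
    *,
    sem: float = 0.0,
) -> DDG:
    """Convert a target-product fraction to ddG = R*T*ln(p/(1-p)) in kJ/mol.

    The SEM propagates by the delta method: sem(ddG) = R*T*sem(p)/(p*(1-p)).
    Undefined at p = 0 or 1 (selectivity at bound).
    """
    if isinstance(p, SelectivityValue):
        sem = p.sem
        p = p.p_target
    if not 0.0 < p < 1.0:
        raise ValueError(f"selectivity at bound (p={p}); ddG undefined")
    rt = GAS_CONSTANT_KJ * temperature
    value = rt * math.log(p / (1.0 - p))
    return DDG(value, rt * sem / (p * (1.0 - p)), temperature)


def ddg_to_selectivity(ddg: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Inverse of :func:`selectivity_to_ddg` (logistic in ddG/RT)."""
    rt = GAS_CONSTANT_KJ * temperature
    return 1.0 / (1.0 + math.exp(-ddg / rt))


def compute_pfr(ncr: float, ce: float) -> float:
    """Product formation rate = NADPH consumption rate x coupling efficiency.

    ``ce`` is a fraction in [0, 1]; values above 1 almost always mean a
    percentage was not converted and are rejected.
    """
    if ncr < 0:
        raise ValueError(f"ncr must be >= 0, got {ncr}")
    if not 0.0 <= ce <= 1.0:
        raise ValueError(f"ce must be a fraction in [0, 1], got {ce}")
    return ncr * ce


def compute_ce(pfr: float, ncr: float) -> float:
    """Coupling efficiency = PFR / NCR (so compute_pfr(ncr, ce) == pfr)."""
    if ncr <= 0:
        raise ValueError(f"ncr must be > 0, got {ncr}")
    return pfr / ncr


def compute_ttf(ttn: float, elapsed: float) -> float:
    """Total turnover frequency = TTN / elapsed time (minutes)."""
    if elapsed <= 0:
        raise ValueError(f"elapsed must be > 0, got {elapsed}")
    return ttn / elapsed


def correct_ncr(raw_rate: float, leak_rate: float) -> tuple[float, bool]:
    """Subtract the substrate-free NADPH leak rate from the raw rate.

    Returns ``(corrected, leak_exceeds)``: a negative corrected rate (leak
    above consumption, common for poorly coupled mutants) is flagged, not
    clamped.
    """
    if raw_rate < 0 or leak_rate < 0:
        raise ValueError("rates must be >= 0")
    corrected = raw_rate - leak_rate
    return corrected, corrected < 0


# ---------------------------------------------------------------------------
# dataset-level derivation

_FORMULAS = ("ddg", "pfr", "ce", "ttf", "ncr_corrected")


def _derive_value(formula: str, inputs: Sequence[float], params: Mapping) -> float:
    if formula == "ddg":
        p = inputs[0] / (100.0 if params.get("percent", True) else 1.0)
        return selectivity_to_ddg(p, params.get("temperature", STANDARD_TEMPERATURE)).value
    if formula == "pfr":
        ncr, ce = inputs
        return compute_pfr(ncr, ce / (100.0 if params.get("ce_percent", True) else 1.0))
    if formula == "ce":
        scale = 100.0 if params.get("percent", True) else 1.0
        return scale * compute_ce(inputs[0], inputs[1])
    if formula == "ttf":
        return compute_ttf(inputs[0], params.get("elapsed", 1.0))
    if formula == "ncr_corrected":
        return correct_ncr(inputs[0], inputs[1])[0]
    raise ValueError(f"unknown formula {formula!r}; expected one of {_FORMULAS}")


def _delta_sem(formula: str, means: Sequence[float], sems: Sequence[float], params: Mapping) -> float:
    """First-order (delta-method) SEM of each derived trait."""
    if formula == "ddg":
        scale = 100.0 if params.get("percent", True) else 1.0
        p = means[0] / scale
        rt = GAS_CONSTANT_KJ * params.get("temperature", STANDARD_TEMPERATURE)
        return rt * (sems[0] / scale) / (p * (1.0 - p))
    if formula == "pfr":
        scale = 100.0 if params.get("ce_percent", True) else 1.0
        ncr, ce = means[0], means[1] / scale
        return math.hypot(ce * sems[0], ncr * sems[1] / scale)
    if formula == "ce":
        scale = 100.0 if params.get("percent", True) else 1.0
        pfr, ncr = means
        return scale * math.hypot(sems[0] / ncr, pfr * sems[1] / ncr**2)
    if formula == "ttf":
        return sems[0] / params.get("elapsed", 1.0)
    if formula == "ncr_corrected":
        return math.hypot(sems[0], sems[1])
    raise ValueError(f"unknown formula {formula!r}")


def augment_dataset(
    dataset: DeconvolutionDataset,
    specs: Sequence[Mapping],
    *,
    force: bool = False,
) -> list[str]:
    """Add derived traits to a dataset in place.

    Each spec is a mapping with keys ``name``, ``formula`` (one of ``ddg``,
    ``pfr``, ``ce``, ``ttf``, ``ncr_corrected``), ``inputs`` (input trait
    names) and optional formula parameters (``percent``, ``ce_percent``,
    ``elapsed``, ``temperature``, ``units``, ``higher_is_better``,
    ``precision``).  Values are computed per replicate when every input
    carries replicates with matching n; otherwise from the means with a
    delta-method SEM.  Returns a list of warnings for skipped derivations;
    an existing trait is only overwritten with ``force=True``.
    """
    warnings: list[str] = []
    for spec in specs:
        name = spec["name"]
        formula = spec["formula"]
        inputs = list(spec["inputs"])
        if name in dataset.traits and not force:
            warnings.append(f"trait {name!r} already present; skipped (use force)")
            continue
        missing = [t for t in inputs if t not in dataset.traits]
        if missing:
            warnings.append(f"derived trait {name!r}: missing input trait(s) {missing}")
            continue
        definition = TraitDefinition(
            name=name,
            units=spec.get("units", "kJ/mol" if formula == "ddg" else ""),
            higher_is_better=spec.get("higher_is_better", True),
            kind="derived",
            inputs=tuple(inputs),
            precision=spec.get("precision", 1),
        )
        if name in dataset.traits:
            dataset.traits[name] = definition
        else:
            dataset.define_trait(definition)

        for genotype in dataset.genotypes():
            if not all(dataset.has(genotype, t) for t in inputs):
                continue
            ms = [dataset.get(genotype, t) for t in inputs]
            per_replicate = all(m.replicates is not None for m in ms) and (
                len({m.n for m in ms}) == 1
            )
            try:
                if per_replicate:
                    values = [
                        _derive_value(formula, [m.replicates[i] for m in ms], spec)
                        for i in range(ms[0].n)
                    ]
                    measurement = Measurement.from_replicates(genotype, name, values)
                else:
                    mean = _derive_value(formula, [m.mean for m in ms], spec)
                    sem = _delta_sem(formula, [m.mean for m in ms], [m.sem for m in ms], spec)
                    measurement = Measurement(genotype, name, mean, sem, ms[0].n)
            except ValueError as exc:
                warnings.append(f"{name!r} for {genotype.label}: {exc}")
                continue
            dataset.add(measurement, replace_existing=force)
    return warnings
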