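"""Tabular input/output and YAML run configuration.

Input schema (CSV or TSV, header required, UTF-8, genotype strings
case-sensitive): one of

* replicate form — columns ``genotype, trait, value``, one row per replicate;
* summary form   — columns ``genotype, trait, mean, sem`` and optional ``n``.

Results are written as CSV (flat), JSON (full precision, including part
effects and thresholds) or a Markdown matrix whose cells read like
``+SE 9.0`` — the interaction class followed by epsilon rounded to the
trait's display precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .datamodel import (
    DatasetError,
    DeconvolutionDataset,
    Genotype,
    Measurement,
    STANDARD_TEMPERATURE,
    TraitDefinition,
    parse_genotype,
)
from .epistasis import EpistasisTable
from .pathways import PathwayClassification

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_results",
    "epistasis_frame",
    "epistasis_markdown",
    "pathway_frame",
    "load_config",
    "trait_definitions_from_config",
]


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_dataset(
    path: str | Path,
    *,
    sites: Sequence[str] | None = None,
    trait_definitions: Mapping[str, TraitDefinition] | None = None,
    temperature: float = STANDARD_TEMPERATURE,
    strict_labels: bool = False,
    require_parent: bool = True,
) -> DeconvolutionDataset:
    """Read a genotype x trait table into a :class:`DeconvolutionDataset`.

    When ``sites`` is omitted, site labels default to ``site1..siteN`` with N
    taken from the genotype label length.  Non-numeric values raise a
    :class:`DatasetError` naming the offending line.
    """
    path = Path(path)
    sep = _infer_sep(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            raise DatasetError(f"{path}: empty file")
        columns = [c.strip().lower() for c in reader.fieldnames]
        reader.fieldnames = columns
        replicate_form = "value" in columns
        summary_form = "mean" in columns
        if "genotype" not in columns or "trait" not in columns:
            raise DatasetError(f"{path}: need 'genotype' and 'trait' columns")
        if not replicate_form and not summary_form:
            raise DatasetError(f"{path}: need a 'value' or a 'mean'/'sem' column")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            label = (row.get("genotype") or "").strip()
            trait = (row.get("trait") or "").strip()
            if not label or not trait:
                raise DatasetError(f"{path}:{lineno}: missing genotype or trait")
            parsed: dict = {"genotype": label, "trait": trait, "line": lineno}
            numeric = ("value",) if replicate_form else ("mean", "sem")
            for col in numeric:
                raw = (row.get(col) or "").strip()
                try:
                    parsed[col] = float(raw)
                except ValueError:
                    raise DatasetError(
                        f"{path}:{lineno}: non-numeric {col} value {raw!r}"
                    ) from None
            if summary_form:
                raw_n = (row.get("n") or "").strip()
                parsed["n"] = int(raw_n) if raw_n else 1
            rows.append(parsed)
    if not rows:
        raise DatasetError(f"{path}: no measurements")

    if sites is None:
        n = len(rows[0]["genotype"])
        sites = tuple(f"site{i + 1}" for i in range(n))

    dataset = DeconvolutionDataset(sites=tuple(sites), temperature=temperature)
    if trait_definitions:
        for definition in trait_definitions.values():
            dataset.define_trait(definition)

    if replicate_form:
        grouped: dict[tuple[str, str], list[float]] = {}
        for row in rows:
            grouped.setdefault((row["genotype"], row["trait"]), []).append(row["value"])
        for (label, trait), values in grouped.items():
            genotype = parse_genotype(label, sites, strict=strict_labels)
            dataset.add(Measurement.from_replicates(genotype, trait, values))
    else:
        for row in rows:
            genotype = parse_genotype(row["genotype"], sites, strict=strict_labels)
            dataset.add(
                Measurement(genotype, row["trait"], row["mean"], row["sem"], row["n"])
            )

    if require_parent:
        parent = dataset.parent
        if not any(g.is_parent for g in dataset.genotypes()):
            raise DatasetError(
                f"{path}: parent genotype {parent.label!r} has no measurements"
            )
    return dataset


def write_dataset(dataset: DeconvolutionDataset, path: str | Path) -> None:
    """Write a dataset in summary form (round-trips means and SEMs)."""
    path = Path(path)
    sep = _infer_sep(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["genotype", "trait", "mean", "sem", "n"])
        for m in dataset.measurements():
            writer.writerow(
                [m.genotype.label, m.trait, repr(m.mean), repr(m.sem), m.n]
            )


# ---------------------------------------------------------------------------
# results rendering


def epistasis_frame(table: EpistasisTable) -> pd.DataFrame:
    """Flat one-row-per-(split, trait) view of an epistasis table."""
    rows = []
    for r in table.results:
        rows.append(
            {
                "type": r.split.kind,
                "combination": r.combination.split(" -> ")[0],
                "resulting_mutant": r.resulting_genotype,
                "trait": r.trait,
                "label": r.label,
                "epsilon": r.epsilon,
                "sem_epsilon": r.sem_epsilon,
                "expected": r.expected,
                "sem_expected": r.sem_expected,
                "observed": r.observed,
                "marginal_parts": ";".join(map(str, r.marginal_parts)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "type",
            "combination",
            "resulting_mutant",
            "trait",
            "label",
            "epsilon",
            "sem_epsilon",
            "expected",
            "sem_expected",
            "observed",
            "marginal_parts",
        ],
    )


def epistasis_markdown(
    table: EpistasisTable,
    trait_definitions: Mapping[str, TraitDefinition] | None = None,
) -> str:
    """Matrix rendering: one row per split, one column per trait.

    Cells carry ``<label> <epsilon>`` with epsilon rounded to the trait's
    display precision, mirroring the conventional epistasis-table layout.
    """
    traits = table.traits
    precisions = {
        t: (trait_definitions[t].precision if trait_definitions and t in trait_definitions else 1)
        for t in traits
    }
    by_split: dict[str, dict] = {}
    order: list[str] = []
    for r in table.results:
        if r.combination not in by_split:
            by_split[r.combination] = {"type": r.split.kind, "mutant": r.resulting_genotype}
            order.append(r.combination)
        by_split[r.combination][r.trait] = r.cell(precisions[r.trait])

    header = ["Type", "Combination", "Resulting mutant"] + list(traits)
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    for combination in order:
        row = by_split[combination]
        cells = [row["type"], combination.split(" -> ")[0], row["mutant"]]
        cells += [row.get(t, "") for t in traits]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def pathway_frame(classifications: Sequence[PathwayClassification], sites: Sequence[str]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        block = c.first_blocking_step
        rows.append(
            {
                "pathway": c.pathway.number,
                "order": " -> ".join(sites[i] for i in c.pathway.ordering),
                "verdict": c.verdict,
                "first_blocking_step": block.index if block else "",
                "blocking_genotype": block.to_label if block else "",
                "blocking_traits": ";".join(block.blocking_traits) if block else "",
            }
        )
    return pd.DataFrame(rows)


def _json_default(obj):
    from dataclasses import asdict, is_dataclass

    if is_dataclass(obj) and not isinstance(obj, type):
        return asdict(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(
    results: EpistasisTable | Sequence[PathwayClassification] | pd.DataFrame,
    path: str | Path,
    format: str = "csv",
    *,
    trait_definitions: Mapping[str, TraitDefinition] | None = None,
    sites: Sequence[str] | None = None,
) -> None:
    """Write analysis results as ``csv``, ``json`` or ``markdown``.

    An empty result list yields a header-only file.
    """
    path = Path(path)
    if format not in ("csv", "json", "markdown"):
        raise ValueError(f"unknown format {format!r}")

    if isinstance(results, EpistasisTable):
        if format == "csv":
            epistasis_frame(results).to_csv(path, index=False)
        elif format == "markdown":
            path.write_text(epistasis_markdown(results, trait_definitions), encoding="utf-8")
        else:
            payload = {
                "mode": results.mode,
                "thresholds": {"k_sig": results.thresholds.k_sig, "abs_tol": results.thresholds.abs_tol},
                "traits": results.traits,
                "results": [
                    {
                        "type": r.split.kind,
                        "combination": r.combination,
                        "resulting_mutant": r.resulting_genotype,
                        "trait": r.trait,
                        "label": r.label,
                        "epsilon": r.epsilon,
                        "sem_epsilon": r.sem_epsilon,
                        "w_parts": list(r.w_parts),
                        "sem_w_parts": list(r.sem_w_parts),
                        "w_combined": r.w_combined,
                        "expected": r.expected,
                        "sem_expected": r.sem_expected,
                        "observed": r.observed,
                        "sem_observed": r.sem_observed,
                        "marginal_parts": list(r.marginal_parts),
                    }
                    for r in results.results
                ],
                "skipped": [list(s) for s in results.skipped],
                "summaries": results.summaries(),
            }
            path.write_text(json.dumps(payload, indent=2, default=_json_default), encoding="utf-8")
    elif isinstance(results, pd.DataFrame):
        if format == "csv":
            results.to_csv(path, index=False)
        elif format == "markdown":
            path.write_text(results.to_markdown(index=False) + "\n", encoding="utf-8")
        else:
            path.write_text(results.to_json(orient="records", indent=2), encoding="utf-8")
    else:  # pathway classifications
        if sites is None:
            raise ValueError("sites required to render pathway results")
        frame = pathway_frame(list(results), sites)
        if format == "csv":
            frame.to_csv(path, index=False)
        elif format == "markdown":
            path.write_text(frame.to_markdown(index=False) + "\n", encoding="utf-8")
        else:
            payload = [
                {
                    "pathway": c.pathway.number,
                    "ordering": [sites[i] for i in c.pathway.ordering],
                    "verdict": c.verdict,
                    "steps": [
                        {
                            "index": s.index,
                            "from": s.from_label,
                            "to": s.to_label,
                            "deltas": s.deltas,
                            "tolerances": s.tolerances,
                            "permitted": s.permitted,
                            "blocking_traits": list(s.blocking_traits),
                        }
                        for s in c.steps
                    ],
                    "reason": c.reason,
                }
                for c in results
            ]
            path.write_text(json.dumps(payload, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise DatasetError(f"{path}: config must be a mapping")
    return config


def trait_definitions_from_config(config: Mapping) -> dict[str, TraitDefinition]:
    """Build :class:`TraitDefinition` objects from the ``traits`` config list."""
    definitions: dict[str, TraitDefinition] = {}
    for entry in config.get("traits", []):
        definition = TraitDefinition(
            name=entry["name"],
            units=entry.get("units", ""),
            higher_is_better=entry.get("higher_is_better", True),
            kind=entry.get("kind", "measured"),
            inputs=tuple(entry.get("inputs", ())),
            precision=entry.get("precision", 1),
        )
        definitions[definition.name] = definition
    return definitions
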