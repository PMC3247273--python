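"""Readers and writers for the plain-text formats used throughout.

Expression matrices travel as TSV (first column gene symbol, header row of
sample ids); annotations and scores as CSV keyed by sample id; gene sets as
GMT with one record per metagene arm (suffixes ``_up`` / ``_dn``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import Metagene, validate_expression

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_csv",
    "write_gmt",
    "read_gmt",
]


def read_expression_tsv(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    return validate_expression(expr, require_finite=False)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_annotation_csv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, index_col=0)
    ann.index = ann.index.astype(str)
    return ann


def write_gmt(metagenes: list[Metagene], path) -> None:
    """One GMT record per arm: ``NAME_up`` / ``NAME_dn``."""
    lines = []
    for mg in metagenes:
        desc = f"coherence={mg.coherence:.4f}" if mg.coherence is not None else "na"
        if mg.positive_arm:
            lines.append("\t".join([f"{mg.name}_up", desc, *mg.positive_arm]))
        if mg.negative_arm:
            lines.append("\t".join([f"{mg.name}_dn", desc, *mg.negative_arm]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> list[Metagene]:
    """Reassemble metagenes from ``_up`` / ``_dn`` GMT records."""
    arms: dict[str, dict[str, tuple[str, ...]]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        record, genes = fields[0], tuple(fields[2:])
        if record.endswith("_up"):
            name, arm = record[:-3], "pos"
        elif record.endswith("_dn"):
            name, arm = record[:-3], "neg"
        else:
            name, arm = record, "pos"
        if name not in arms:
            arms[name] = {}
            order.append(name)
        arms[name][arm] = genes
    return [
        Metagene(name=name, positive_arm=arms[name].get("pos", ()), negative_arm=arms[name].get("neg", ()))
        for name in order
    ]
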