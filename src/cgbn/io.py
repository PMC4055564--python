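"""Readers and writers: mixed delimited tables, PED genotype files, network
exchange formats (TGF / SIF / GraphML) and a JSON serialization that round-
trips a fitted network with its parameters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .model import (
    DISCRETE,
    CGBayesNet,
    CLGNodeParams,
    DAGStructure,
    DiscreteNodeParams,
    MixedDataset,
    VariableSpec,
)


def read_mixed_table(
    path: str | Path,
    phenotype: str,
    delimiter: str = ",",
    kind_overrides: Mapping[str, str] | None = None,
) -> MixedDataset:
    """Read a delimited text table with a header row into a typed dataset.

    Columns containing any non-numeric token become discrete; all-numeric
    columns continuous unless overridden.  Rows with missing cells are
    dropped with a logged count.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty file: {path}") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged/unparseable table {path}: {exc}") from None
    if frame.empty:
        raise ValueError(f"no data rows in {path}")
    if phenotype not in frame.columns:
        raise ValueError(f"phenotype column {phenotype!r} absent from {path}")
    return MixedDataset.from_frame(frame, phenotype, kind_overrides=kind_overrides)


def write_mixed_table(data: MixedDataset, path: str | Path, delimiter: str = ",") -> None:
    data.frame.to_csv(path, sep=delimiter, index=False)


def read_ped(ped_path: str | Path, map_path: str | Path | None = None) -> MixedDataset:
    """Read a canonical PED file (FID IID PAT MAT SEX PHENO allele pairs).

    Each SNP becomes one discrete variable whose states are the sorted
    two-letter genotypes ("AG" == "GA"); rows with a missing allele code "0"
    are dropped (complete-case); the PHENO column (1/2) becomes the
    "control"/"case" phenotype.  SNP names come from the optional MAP file,
    else SNP1..SNPk.
    """
    rows = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 8 or (len(tokens) - 6) % 2 != 0:
                raise ValueError(f"{ped_path}:{line_no}: odd allele count")
            rows.append(tokens)
    if not rows:
        raise ValueError(f"empty PED file {ped_path}")
    n_snps = (len(rows[0]) - 6) // 2
    if any((len(r) - 6) // 2 != n_snps for r in rows):
        raise ValueError(f"inconsistent SNP count in {ped_path}")
    if map_path is not None:
        snp_names = [line.split()[1] for line in open(map_path) if line.strip()]
        if len(snp_names) != n_snps:
            raise ValueError("MAP file SNP count does not match PED")
    else:
        snp_names = [f"SNP{i + 1}" for i in range(n_snps)]
    records = []
    for r in rows:
        pheno = {"1": "control", "2": "case"}.get(r[5])
        if pheno is None:
            continue
        rec = {"phenotype": pheno}
        ok = True
        for i in range(n_snps):
            a, b = r[6 + 2 * i], r[7 + 2 * i]
            if a == "0" or b == "0":
                ok = False
                break
            rec[snp_names[i]] = "".join(sorted((a, b)))
        if ok:
            records.append(rec)
    if not records:
        raise ValueError("no complete records in PED file")
    frame = pd.DataFrame.from_records(records)
    overrides = {c: DISCRETE for c in frame.columns}
    return MixedDataset.from_frame(frame, "phenotype", kind_overrides=overrides)


# -- network exchange formats -------------------------------------------------


def _structure_of(obj: CGBayesNet | DAGStructure) -> tuple[DAGStructure, dict[str, str]]:
    if isinstance(obj, CGBayesNet):
        return obj.structure, {v.name: v.kind for v in obj.variables}
    return obj, {}


def write_network(
    obj: CGBayesNet | DAGStructure, path: str | Path, fmt: str = "tgf"
) -> None:
    """Export a structure as TGF, SIF or GraphML (node/edge counts preserved)."""
    structure, kinds = _structure_of(obj)
    path = Path(path)
    if fmt == "tgf":
        ids = {n: i + 1 for i, n in enumerate(structure.nodes)}
        lines = [f"{ids[n]} {n}" for n in structure.nodes]
        lines.append("#")
        lines += [f"{ids[p]} {ids[c]}" for p, c in sorted(structure.edges)]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "sif":
        lines = [f"{p} dep {c}" for p, c in sorted(structure.edges)]
        connected = {n for e in structure.edges for n in e}
        lines += [n for n in structure.nodes if n not in connected]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        for n in structure.nodes:
            g.add_node(n, kind=kinds.get(n, ""))
        g.add_edges_from(sorted(structure.edges))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (use tgf, sif or graphml)")


# -- JSON round trip ----------------------------------------------------------


def save_network_json(net: CGBayesNet, path: str | Path) -> None:
    doc: dict = {
        "phenotype": net.phenotype,
        "variables": [
            {"name": v.name, "kind": v.kind, "states": list(v.states) if v.states else None}
            for v in net.variables
        ],
        "edges": sorted(list(e) for e in net.structure.edges),
        "params": {},
    }
    for node, p in net.params.items():
        if isinstance(p, DiscreteNodeParams):
            doc["params"][node] = {
                "type": "discrete",
                "parents": list(p.parents),
                "states": list(p.states),
                "cpt": p.cpt.tolist(),
            }
        else:
            doc["params"][node] = {
                "type": "clg",
                "disc_parents": list(p.disc_parents),
                "cont_parents": list(p.cont_parents),
                "intercepts": p.intercepts.tolist(),
                "coefs": p.coefs.tolist(),
                "variances": p.variances.tolist(),
            }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_network_json(path: str | Path) -> CGBayesNet:
    doc = json.loads(Path(path).read_text())
    variables = tuple(
        VariableSpec(v["name"], v["kind"], tuple(v["states"]) if v["states"] else None)
        for v in doc["variables"]
    )
    structure = DAGStructure([v.name for v in variables], [tuple(e) for e in doc["edges"]])
    params: dict[str, DiscreteNodeParams | CLGNodeParams] = {}
    for node, p in doc["params"].items():
        if p["type"] == "discrete":
            params[node] = DiscreteNodeParams(
                tuple(p["parents"]), tuple(p["states"]), np.array(p["cpt"])
            )
        else:
            params[node] = CLGNodeParams(
                tuple(p["disc_parents"]),
                tuple(p["cont_parents"]),
                np.array(p["intercepts"]),
                np.array(p["coefs"]),
                np.array(p["variances"]),
            )
    return CGBayesNet(structure, variables, params, phenotype=doc["phenotype"])
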