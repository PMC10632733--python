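"""On-disk formats: MIDAS response tables, network and perturbation files.

MIDAS (Minimum Information for Data Analysis in Systems Biology) dialect:

* ``TR:<agent>`` — 0/1 treatment indicators, one column per agent;
* ``DA:ALL`` (or ``DA:<readout>``) — acquisition time, constant 30 (min);
* ``DV:<readout>`` — measured value, a linear fold change relative to the
  vehicle control; missing values are written as ``NA``.

Replicates may be encoded either as repeated rows with the same treatment
indicator vector (the dialect written by :func:`write_midas`) or as
suffixed value columns ``DV:<readout>:<rep>``; both are read.

Networks are two-column TSVs (source, target, optional ``+``/``-`` sign
hint) with a companion node-class TSV; perturbation maps are TSVs of
agent, target node, mode.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .data import ResponseDataset
from .structure import NetworkStructure, PerturbationMap, StructureError, condition

ACQUISITION_TIME = 30  # minutes, the study's single time point
NA = "NA"


class MidasFormatError(ValueError):
    pass


# --------------------------------------------------------------------- #
# MIDAS

def write_midas(dataset: ResponseDataset, path) -> None:
    """Write a dataset as MIDAS with replicates as repeated rows."""
    if not dataset.readouts:
        raise MidasFormatError("dataset has no readouts")
    agents = sorted({a for cond in dataset.conditions for a in cond})
    cols = [f"TR:{a}" for a in agents] + ["DA:ALL"] + [f"DV:{r}" for r in dataset.readouts]
    rows = []
    for ci, cond in enumerate(dataset.conditions):
        for rep in range(dataset.n_replicates):
            vals = dataset.values[ci, :, rep]
            row = [1 if a in cond else 0 for a in agents] + [ACQUISITION_TIME]
            row += [v if np.isfinite(v) else NA for v in vals]
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_midas(path, cell_line: str = "") -> ResponseDataset:
    """Read a MIDAS file into a :class:`ResponseDataset`.

    Conditions are the distinct treatment-indicator vectors; repeated rows
    (or ``DV:<readout>:<rep>`` columns) become replicates.  The all-zeros
    vehicle-control condition must be present.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    tr_cols, dv_cols, da_cols = [], [], []
    for col in df.columns:
        prefix = col.split(":", 1)[0]
        if prefix == "TR":
            tr_cols.append(col)
        elif prefix == "DV":
            dv_cols.append(col)
        elif prefix == "DA":
            da_cols.append(col)
        else:
            raise MidasFormatError(f"unknown column prefix in column {col!r}")
    if not tr_cols or not dv_cols:
        raise MidasFormatError("MIDAS file must declare TR: and DV: columns")
    agents = [c.split(":", 1)[1] for c in tr_cols]

    # detect replicate-suffix dialect: DV:<readout>:<rep>
    suffixed = [c for c in dv_cols if len(c.split(":")) == 3 and c.split(":")[2].isdigit()]
    wide = bool(suffixed) and len(suffixed) == len(dv_cols)

    tr = df[tr_cols].fillna(0).astype(int).to_numpy()
    conds = [condition([a for a, flag in zip(agents, row) if flag]) for row in tr]

    if wide:
        readouts = list(dict.fromkeys(c.split(":")[1] for c in dv_cols))
        reps = sorted({int(c.split(":")[2]) for c in dv_cols})
        uniq: list[tuple[str, ...]] = []
        for c in conds:
            if c not in uniq:
                uniq.append(c)
        if len(uniq) != len(conds):
            raise MidasFormatError("duplicate condition rows in replicate-column dialect")
        values = np.full((len(uniq), len(readouts), len(reps)), np.nan)
        for i, _cond in enumerate(uniq):
            for j, r in enumerate(readouts):
                for k, rep in enumerate(reps):
                    col = f"DV:{r}:{rep}"
                    if col in df.columns:
                        values[i, j, k] = pd.to_numeric(df[col], errors="coerce").iloc[i]
    else:
        readouts = [c.split(":", 1)[1] for c in dv_cols]
        uniq = []
        groups: dict[tuple[str, ...], list[int]] = {}
        for i, c in enumerate(conds):
            if c not in groups:
                uniq.append(c)
                groups[c] = []
            groups[c].append(i)
        n_rep = max(len(g) for g in groups.values())
        values = np.full((len(uniq), len(readouts), n_rep), np.nan)
        dv = df[dv_cols].apply(pd.to_numeric, errors="coerce").to_numpy()
        for i, c in enumerate(uniq):
            for k, row_idx in enumerate(groups[c]):
                values[i, :, k] = dv[row_idx]

    if () not in uniq:
        raise MidasFormatError("vehicle control (all-zeros treatment row) missing")
    return ResponseDataset(uniq, list(readouts), values, cell_line=cell_line)


# --------------------------------------------------------------------- #
# network structure and perturbation map

_SIGNS = {"+": 1, "-": -1, "−": -1}


def read_network(links_path, classes_path) -> NetworkStructure:
    """Read a link-list TSV and a node-class TSV into a structure.

    The link file has columns source, target and an optional ``+``/``-``
    sign hint; every node referenced must appear in the class file.
    """
    links_df = pd.read_csv(links_path, sep="\t", header=None, comment="#",
                           names=["source", "target", "sign"], dtype=str)
    classes_df = pd.read_csv(classes_path, sep="\t", header=None, comment="#",
                             names=["node", "cls"], dtype=str)
    node_classes = dict(zip(classes_df["node"], classes_df["cls"]))
    nodes = tuple(classes_df["node"])
    links, hints = [], {}
    for _, row in links_df.iterrows():
        src, tgt = row["source"], row["target"]
        for n in (src, tgt):
            if n not in node_classes:
                raise StructureError(f"link references node {n!r} missing from class file")
        links.append((src, tgt))
        if isinstance(row["sign"], str) and row["sign"].strip():
            sign = row["sign"].strip()
            if sign not in _SIGNS:
                raise StructureError(f"unknown sign hint {sign!r} for {src}->{tgt}")
            hints[(src, tgt)] = _SIGNS[sign]
    return NetworkStructure(nodes, tuple(links), node_classes, hints)


def write_network(structure: NetworkStructure, links_path, classes_path) -> None:
    with open(links_path, "w") as fh:
        for s, t in structure.links:
            hint = structure.sign_hints.get((s, t))
            suffix = "" if hint is None else ("\t+" if hint > 0 else "\t-")
            fh.write(f"{s}\t{t}{suffix}\n")
    with open(classes_path, "w") as fh:
        for n in structure.nodes:
            fh.write(f"{n}\t{structure.node_classes.get(n, 'enzyme')}\n")


def read_perturbation_map(path) -> PerturbationMap:
    """Read a TSV of agent, target node, mode (inhibition/stimulation)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["agent", "target", "mode"], dtype=str)
    entries: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        agent = row["agent"]
        if agent in entries:
            raise StructureError(f"agent {agent!r} declared with two targets")
        entries[agent] = (row["target"], row["mode"])
    return PerturbationMap(entries)


def write_perturbation_map(pmap: PerturbationMap, path) -> None:
    with open(path, "w") as fh:
        for agent in pmap.agents:
            target, mode = pmap.entries[agent]
            fh.write(f"{agent}\t{target}\t{mode}\n")


# --------------------------------------------------------------------- #
# fitted-model JSON

def read_model_json(path):
    """Load a fit written by :meth:`MRAResults.to_json`.

    Returns ``(structure, perturbation_map, params_dict, meta)``.
    """
    with open(path) as fh:
        d = json.load(fh)
    classes = d.get("node_classes") or {}
    structure = NetworkStructure(tuple(d["nodes"]),
                                 tuple(tuple(l) for l in d["links"]), classes)
    pmap = PerturbationMap({a: tuple(v) for a, v in d["perturbation_map"].items()})
    meta = {k: d.get(k) for k in ("cell_line", "ssr", "n_data", "n_params",
                                  "start_seed", "n_starts", "converged_fraction")}
    return structure, pmap, d["params"], meta
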