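"""Panel data containers, I/O and preprocessing.

Multi-wave panel data are held as a persons x waves x nodes array plus an
observation mask; every downstream stage (estimation, bootstrap, reporting)
consumes this container.  CSV input is accepted in long layout (one row per
person-wave) or wide layout (``{node}_{wave}`` columns); long is canonical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeSpec",
    "PanelDataset",
    "read_panel",
    "write_panel",
    "read_node_specs",
    "write_node_specs",
    "rescale_to_likert",
    "complete_case_filter",
]

_ROLES = ("symptom", "biomarker", "covariate")


@dataclass(frozen=True)
class NodeSpec:
    """One network node (variable) and how to rescale it.

    Parameters
    ----------
    name : str
        Short unique identifier, used as the CSV column name.
    label : str
        Human-readable label.
    role : {"symptom", "biomarker", "covariate"}
        Substantive role of the node in the network.
    observed_min, observed_max : float, optional
        Bounds used by :func:`rescale_to_likert`.  When ``None`` the pooled
        observed minimum/maximum over all waves is used.
    """

    name: str
    label: str = ""
    role: str = "biomarker"
    observed_min: float | None = None
    observed_max: float | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}, got {self.role!r}")
        if (
            self.observed_min is not None
            and self.observed_max is not None
            and not self.observed_min < self.observed_max
        ):
            raise ValueError(
                f"node {self.name!r}: observed_min must be < observed_max"
            )


@dataclass
class PanelDataset:
    """Persons x waves x nodes numeric panel with an observation mask.

    ``values[i, t, j]`` is person ``i``'s score on node ``j`` at wave ``t``;
    ``mask[i, t, j]`` is True when that cell was observed.  Masked cells carry
    no information: estimation never reads them (they are stored as NaN).
    """

    values: np.ndarray
    mask: np.ndarray
    person_ids: list = field(default_factory=list)
    wave_labels: list = field(default_factory=list)
    nodes: list[NodeSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be persons x waves x nodes")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        n, T, p = self.values.shape
        if not self.person_ids:
            self.person_ids = list(range(1, n + 1))
        if not self.wave_labels:
            self.wave_labels = list(range(1, T + 1))
        if not self.nodes:
            self.nodes = [NodeSpec(name=f"x{j + 1}") for j in range(p)]
        if len(self.person_ids) != n or len(self.wave_labels) != T:
            raise ValueError("person_ids/wave_labels length mismatch")
        if len(self.nodes) != p:
            raise ValueError("nodes length mismatch")
        names = [nd.name for nd in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        if T < 2:
            raise ValueError("at least 2 waves required")
        per_person = self.mask.any(axis=(1, 2))
        if not per_person.all():
            bad = [self.person_ids[i] for i in np.flatnonzero(~per_person)]
            raise ValueError(f"persons with no observed cells: {bad}")
        # masked cells carry no information
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_waves(self) -> int:
        return self.values.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[2]

    @property
    def node_names(self) -> list[str]:
        return [nd.name for nd in self.nodes]

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            values=self.values.copy(),
            mask=self.mask.copy(),
            person_ids=list(self.person_ids),
            wave_labels=list(self.wave_labels),
            nodes=list(self.nodes),
        )

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (n, T*p) stacked values and mask, wave-major order."""
        n = self.n_persons
        return self.values.reshape(n, -1), self.mask.reshape(n, -1)

    def subset_persons(self, idx: Sequence[int]) -> "PanelDataset":
        idx = np.asarray(idx, dtype=int)
        return PanelDataset(
            values=self.values[idx],
            mask=self.mask[idx],
            person_ids=[self.person_ids[i] for i in idx],
            wave_labels=list(self.wave_labels),
            nodes=list(self.nodes),
        )


def _specs_for(names: Sequence[str], node_specs) -> list[NodeSpec]:
    if node_specs is None:
        return [NodeSpec(name=n) for n in names]
    by_name = {nd.name: nd for nd in node_specs}
    return [by_name.get(n, NodeSpec(name=n)) for n in names]


def read_panel(
    path,
    layout: str = "long",
    node_specs: Sequence[NodeSpec] | None = None,
    person_col: str = "person",
    wave_col: str = "wave",
) -> PanelDataset:
    """Read a panel CSV into a :class:`PanelDataset`.

    Long layout needs ``person`` and ``wave`` columns plus one column per
    node; wide layout needs ``person`` plus ``{node}_{wave}`` columns.
    Empty cells become masked entries.  Waves are ordered ascending.
    """
    df = pd.read_csv(path)
    if layout == "long":
        for col in (person_col, wave_col):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        dup = df.duplicated(subset=[person_col, wave_col], keep=False)
        if dup.any():
            keys = df.loc[dup, [person_col, wave_col]].drop_duplicates()
            pairs = [tuple(r) for r in keys.itertuples(index=False)]
            raise ValueError(f"duplicate (person, wave) rows: {pairs}")
        node_names = [c for c in df.columns if c not in (person_col, wave_col)]
        if node_specs is not None:
            known = {nd.name for nd in node_specs}
            unknown = [c for c in node_names if c not in known]
            if unknown:
                raise ValueError(f"unknown node columns: {unknown}")
            node_names = [nd.name for nd in node_specs if nd.name in node_names]
        persons = sorted(df[person_col].unique().tolist())
        waves = sorted(df[wave_col].unique().tolist())
        n, T, p = len(persons), len(waves), len(node_names)
        values = np.full((n, T, p), np.nan)
        pidx = {pid: i for i, pid in enumerate(persons)}
        widx = {w: t for t, w in enumerate(waves)}
        for _, row in df.iterrows():
            i, t = pidx[row[person_col]], widx[row[wave_col]]
            for j, name in enumerate(node_names):
                values[i, t, j] = row[name]
        mask = ~np.isnan(values)
        return PanelDataset(
            values=values,
            mask=mask,
            person_ids=persons,
            wave_labels=waves,
            nodes=_specs_for(node_names, node_specs),
        )
    if layout == "wide":
        if person_col not in df.columns:
            raise ValueError(f"missing required column {person_col!r}")
        if df[person_col].duplicated().any():
            dups = df.loc[df[person_col].duplicated(), person_col].tolist()
            raise ValueError(f"duplicate person rows: {dups}")
        pairs = []
        for c in df.columns:
            if c == person_col:
                continue
            name, _, wave = c.rpartition("_")
            if not name or not wave.isdigit():
                raise ValueError(f"cannot parse wide column {c!r} as node_wave")
            pairs.append((name, int(wave), c))
        node_names = sorted({name for name, _, _ in pairs})
        if node_specs is not None:
            known = {nd.name for nd in node_specs}
            unknown = [nm for nm in node_names if nm not in known]
            if unknown:
                raise ValueError(f"unknown node columns: {unknown}")
            node_names = [nd.name for nd in node_specs if nd.name in node_names]
        waves = sorted({w for _, w, _ in pairs})
        persons = df[person_col].tolist()
        n, T, p = len(persons), len(waves), len(node_names)
        values = np.full((n, T, p), np.nan)
        widx = {w: t for t, w in enumerate(waves)}
        jidx = {nm: j for j, nm in enumerate(node_names)}
        for name, wave, col in pairs:
            values[:, widx[wave], jidx[name]] = df[col].to_numpy(dtype=float)
        mask = ~np.isnan(values)
        return PanelDataset(
            values=values,
            mask=mask,
            person_ids=persons,
            wave_labels=waves,
            nodes=_specs_for(node_names, node_specs),
        )
    raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def write_panel(data: PanelDataset, path, layout: str = "long") -> None:
    """Write a panel CSV (long or wide); masked cells become empty fields."""
    names = data.node_names
    if layout == "long":
        rows = []
        for i, pid in enumerate(data.person_ids):
            for t, w in enumerate(data.wave_labels):
                row = {"person": pid, "wave": w}
                for j, nm in enumerate(names):
                    row[nm] = data.values[i, t, j] if data.mask[i, t, j] else np.nan
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif layout == "wide":
        cols = {"person": data.person_ids}
        for j, nm in enumerate(names):
            for t, w in enumerate(data.wave_labels):
                col = data.values[:, t, j].copy()
                col[~data.mask[:, t, j]] = np.nan
                cols[f"{nm}_{w}"] = col
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def read_node_specs(path) -> list[NodeSpec]:
    with open(path) as fh:
        raw = json.load(fh)
    return [NodeSpec(**entry) for entry in raw]


def write_node_specs(nodes: Sequence[NodeSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {
                    "name": nd.name,
                    "label": nd.label,
                    "role": nd.role,
                    "observed_min": nd.observed_min,
                    "observed_max": nd.observed_max,
                }
                for nd in nodes
            ],
            fh,
            indent=2,
        )


def rescale_to_likert(data: PanelDataset) -> PanelDataset:
    """Affinely map each node's observed range onto [1, 4].

    Each observed value ``x`` becomes ``1 + 3 (x - min) / (max - min)`` with
    the node's bounds taken from its :class:`NodeSpec` or, by default, the
    pooled observed min/max across all waves — one affine map per node, so
    temporal comparability is preserved.  Putting every node on the same
    1-4 scale (the CES-D response scale) removes scale-variance artefacts
    from the network weights.
    """
    out = data.copy()
    new_nodes = []
    for j, nd in enumerate(data.nodes):
        obs = data.values[:, :, j][data.mask[:, :, j]]
        lo = nd.observed_min if nd.observed_min is not None else (obs.min() if obs.size else np.nan)
        hi = nd.observed_max if nd.observed_max is not None else (obs.max() if obs.size else np.nan)
        if not np.isfinite(lo) or not np.isfinite(hi) or hi <= lo:
            raise ValueError(
                f"node {nd.name!r} has degenerate range [{lo}, {hi}]; "
                "cannot rescale a constant node"
            )
        out.values[:, :, j] = 1.0 + 3.0 * (data.values[:, :, j] - lo) / (hi - lo)
        new_nodes.append(replace(nd, observed_min=float(lo), observed_max=float(hi)))
    out.values = np.where(out.mask, out.values, np.nan)
    out.nodes = new_nodes
    return out


def complete_case_filter(data: PanelDataset, scope: str = "all_waves") -> PanelDataset:
    """Drop persons with missing cells.

    ``scope="all_waves"`` keeps only persons with zero masked cells;
    ``scope="any_wave"`` keeps persons with at least one fully observed wave.
    """
    if scope == "all_waves":
        keep = data.mask.all(axis=(1, 2))
    elif scope == "any_wave":
        keep = data.mask.all(axis=2).any(axis=1)
    else:
        raise ValueError(f"scope must be 'all_waves' or 'any_wave', got {scope!r}")
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("complete-case filter removed every person")
    return data.subset_persons(idx)
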