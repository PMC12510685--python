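"""SWC neuron-reconstruction morphometry.

Reads standard 7-column SWC files, computes the morphometrics used to
compare against the dMRS estimates — branch (segment) length, branching
order and total process length — and the cerebellar layer-thickness proxy
of the sphere fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SWCNeuron",
    "LayerThicknesses",
    "BranchStats",
    "read_swc",
    "branch_stats",
    "layer_fraction_proxy",
    "neuron_summary",
    "write_swc",
]

SOMA_CODE = 1


@dataclass
class SWCNeuron:
    """Validated SWC reconstruction: one tree, soma samples collapsed to root."""

    samples: pd.DataFrame  # columns: id, code, x, y, z, radius, parent
    label: str = ""
    age: float | None = None
    region: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class LayerThicknesses:
    """Cerebellar cortical layer thicknesses in µm.

    EGL/IGL, GL and PL are the soma-rich ("sphere-like") layers; ML is the
    fibre-rich molecular layer. ``wm`` optionally adds white matter to the
    fibre-like side.
    """

    egl_igl: float = 0.0
    gl: float = 0.0
    pl: float = 0.0
    ml: float = 0.0
    wm: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.egl_igl, self.gl, self.pl, self.ml, self.wm)
        if any(v < 0 for v in vals):
            raise ValueError("thicknesses must be >= 0")
        if all(v == 0 for v in vals):
            raise ValueError("at least one thickness must be nonzero")


@dataclass
class BranchStats:
    """Morphometrics of one reconstruction."""

    branch_lengths: np.ndarray  # µm, one entry per branch
    branch_orders: np.ndarray  # bifurcations on root path, per branch
    total_length: float  # µm
    mean_branch_length: float
    max_order: int
    soma_only: bool = False


def read_swc(path: str, label: str = "", age: float | None = None, region: str = "") -> SWCNeuron:
    """Parse and validate a whitespace-delimited SWC file.

    '#' comment lines are ignored. Each sample's parent must be declared on
    an earlier line (or be −1, exactly once); cycles, orphan parents and
    duplicate ids raise a parse error naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                sid, code, parent = int(parts[0]), int(parts[1]), int(parts[6])
                x, y, z, radius = map(float, parts[2:6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if not all(np.isfinite(v) for v in (x, y, z, radius)):
                raise ValueError(f"{path}:{lineno}: non-finite coordinate")
            rows.append((lineno, sid, code, x, y, z, radius, parent))

    seen: dict[int, int] = {}
    n_roots = 0
    for lineno, sid, code, *_rest, parent in rows:
        if sid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {sid}")
        if parent == -1:
            n_roots += 1
        elif parent not in seen:
            raise ValueError(f"{path}:{lineno}: parent {parent} not declared earlier")
        seen[sid] = lineno
    if n_roots != 1:
        raise ValueError(f"{path}: expected exactly one root (parent -1), found {n_roots}")

    df = pd.DataFrame(
        [(sid, code, x, y, z, radius, parent) for _, sid, code, x, y, z, radius, parent in rows],
        columns=["id", "code", "x", "y", "z", "radius", "parent"],
    )
    return SWCNeuron(samples=df, label=label, age=age, region=region)


def write_swc(path: str, neuron: SWCNeuron) -> None:
    with open(path, "w") as fh:
        fh.write("# id code x y z radius parent\n")
        for row in neuron.samples.itertuples(index=False):
            fh.write(f"{row.id} {row.code} {row.x:g} {row.y:g} {row.z:g} {row.radius:g} {row.parent}\n")


def _collapse_soma(neuron: SWCNeuron):
    """Map soma samples to one root node; return (ids, parents, xyz, is_soma)."""
    df = neuron.samples
    soma_ids = set(df.loc[df["code"] == SOMA_CODE, "id"])
    root_id = int(df.loc[df["parent"] == -1, "id"].iloc[0])
    # every soma sample is treated as the root point
    remap = {sid: root_id for sid in soma_ids}

    ids = df["id"].to_numpy()
    parents = df["parent"].to_numpy()
    eff_parent = {}
    for sid, par in zip(ids, parents):
        sid_m = remap.get(sid, sid)
        par_m = remap.get(par, par) if par != -1 else -1
        if sid_m == par_m:  # soma-internal edge
            continue
        eff_parent[sid_m] = par_m
    xyz = {int(r.id): np.array([r.x, r.y, r.z]) for r in df.itertuples(index=False)}
    # the collapsed root keeps the root sample's position
    return root_id, eff_parent, xyz


def branch_stats(neuron: SWCNeuron) -> BranchStats:
    """Branch length, branching order and total process length.

    Branches are delimited by the root, bifurcation points and terminations;
    a branch's length is the summed Euclidean distance along its samples.
    Branching order counts the bifurcations on the path from the root
    (nodes with 3+ children increment the order once). Soma samples are
    collapsed to a single root node and soma-internal edges are excluded
    from the total process length.
    """
    root_id, eff_parent, xyz = _collapse_soma(neuron)
    children: dict[int, list[int]] = {}
    for sid, par in eff_parent.items():
        children.setdefault(par, []).append(sid)
    if not children.get(root_id):
        return BranchStats(
            branch_lengths=np.empty(0), branch_orders=np.empty(0, dtype=int),
            total_length=0.0, mean_branch_length=0.0, max_order=0, soma_only=True,
        )

    def edge_len(a: int, b: int) -> float:
        return float(np.linalg.norm(xyz[a] - xyz[b]))

    branch_lengths: list[float] = []
    branch_orders: list[int] = []
    # walk branches: start at root (order 0) and at every branching node
    stack = [(root_id, c, 0) for c in children[root_id]]
    if len(children[root_id]) > 1:
        # multiple primary processes leave the root; the root itself is a
        # branch point but contributes order 0 to its primaries
        pass
    while stack:
        start, nxt, order = stack.pop()
        length = edge_len(start, nxt)
        node = nxt
        while len(children.get(node, [])) == 1:
            child = children[node][0]
            length += edge_len(node, child)
            node = child
        branch_lengths.append(length)
        branch_orders.append(order)
        kids = children.get(node, [])
        if len(kids) >= 2:  # bifurcation (or trifurcation: order increments once)
            for c in kids:
                stack.append((node, c, order + 1))

    lengths = np.asarray(branch_lengths)
    orders = np.asarray(branch_orders, dtype=int)
    return BranchStats(
        branch_lengths=lengths,
        branch_orders=orders,
        total_length=float(np.sum(lengths)),
        mean_branch_length=float(np.mean(lengths)),
        max_order=int(np.max(orders)),
    )


def layer_fraction_proxy(t: LayerThicknesses) -> float:
    """Layer-thickness proxy of the sphere fraction.

    Ratio of the soma-rich layer thicknesses (EGL/IGL + GL + PL) to the
    total included thickness; the fibre-like side is ML plus any white
    matter term, so adding WM strictly lowers the proxy.
    """
    sphere_like = t.egl_igl + t.gl + t.pl
    total = sphere_like + t.ml + t.wm
    return sphere_like / total


def neuron_summary(neurons: list[SWCNeuron]) -> pd.DataFrame:
    """Per-neuron CSV-ready summary of the headline morphometrics."""
    rows = []
    for n in neurons:
        st = branch_stats(n)
        rows.append({
            "label": n.label, "age": n.age, "region": n.region,
            "mean_L_segment": st.mean_branch_length,
            "max_order": st.max_order,
            "total_length": st.total_length,
        })
    return pd.DataFrame(rows)
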