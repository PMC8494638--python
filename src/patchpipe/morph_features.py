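"""Neuronal morphology: SWC I/O, corrections, laminar histograms, morphometrics.

Coordinate convention: reconstructions are pia-aligned with the pia surface at
``y = LayerContext.pia_y`` and ``y`` increasing toward the pia, so cortical
depth of a node is ``pia_y - y`` (positive below the pia).  SWC files use the
standard 7 columns (id, type, x, y, z, radius, parent), 1-based ids, type
codes 1 soma / 2 axon / 3 basal dendrite / 4 apical dendrite, coordinates in
micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Morphology",
    "LayerContext",
    "read_swc",
    "write_swc",
    "correct_shrinkage",
    "correct_tilt",
    "laminar_histogram",
    "apical_hist_pc0",
    "morphometrics",
    "SOMA",
    "AXON",
    "BASAL",
    "APICAL",
]

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
_KNOWN_TYPES = {SOMA, AXON, BASAL, APICAL}
SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


@dataclass
class Morphology:
    """Typed node tree stored as a node table (SWC columns).

    Exactly one root (parent -1) of type soma; additional roots are permitted
    only for disconnected axon fragments.  Parents must precede children.
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.nodes.reset_index(drop=True).copy()
        missing = set(SWC_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"node table missing columns: {sorted(missing)}")
        df = df[SWC_COLUMNS]
        df[["id", "type", "parent"]] = df[["id", "type", "parent"]].astype(int)
        df[["x", "y", "z", "radius"]] = df[["x", "y", "z", "radius"]].astype(float)
        if df["id"].duplicated().any():
            raise ValueError("duplicate node ids")
        seen: set[int] = set()
        roots = []
        for nid, ntype, parent in zip(df["id"], df["type"], df["parent"]):
            if parent == nid:
                raise ValueError(f"node {nid} is its own parent")
            if parent == -1:
                roots.append((nid, ntype))
            elif parent not in seen:
                raise ValueError(
                    f"node {nid}: parent {parent} undefined or does not precede it"
                )
            seen.add(nid)
        soma_roots = [nid for nid, t in roots if t == SOMA]
        if len(soma_roots) != 1:
            raise ValueError(f"expected exactly one soma root, found {len(soma_roots)}")
        for nid, t in roots:
            if t != SOMA and t != AXON:
                raise ValueError(f"non-axon root of type {t} (node {nid})")
        unknown = set(df["type"]) - _KNOWN_TYPES
        if unknown:
            warnings.warn(f"unknown SWC type codes preserved: {sorted(unknown)}")
        self.nodes = df

    @property
    def soma(self) -> pd.Series:
        df = self.nodes
        return df[(df["parent"] == -1) & (df["type"] == SOMA)].iloc[0]

    def of_type(self, *types: int) -> pd.DataFrame:
        return self.nodes[self.nodes["type"].isin(types)]

    def segments(self, *types: int) -> pd.DataFrame:
        """Inter-node segments whose child node is of one of ``types``.

        Returns a frame with child/parent coordinates and Euclidean length.
        """
        df = self.nodes
        idx = df.set_index("id")
        child = df[(df["parent"] != -1) & df["type"].isin(types)]
        par = idx.loc[child["parent"]]
        out = pd.DataFrame(
            {
                "x0": par["x"].to_numpy(),
                "y0": par["y"].to_numpy(),
                "z0": par["z"].to_numpy(),
                "x1": child["x"].to_numpy(),
                "y1": child["y"].to_numpy(),
                "z1": child["z"].to_numpy(),
            }
        )
        out["length"] = np.sqrt(
            (out["x1"] - out["x0"]) ** 2
            + (out["y1"] - out["y0"]) ** 2
            + (out["z1"] - out["z0"]) ** 2
        )
        return out


@dataclass
class LayerContext:
    """Pia position and laminar boundary depths (um below pia) for a specimen.

    ``boundaries`` maps boundary names (e.g. ``"L1/2"``, ``"L3/4"``, ``"wm"``)
    to depths; depths must be strictly increasing in the canonical order
    L1/2, L2/3, L3/4, L4/5, L5/6, wm (L2/3 optional, trailing ones optional).
    """

    pia_y: float
    boundaries: dict[str, float]
    soma_depth: float | None = None

    _ORDER = ("L1/2", "L2/3", "L3/4", "L4/5", "L5/6", "wm")

    def __post_init__(self) -> None:
        depths = [self.boundaries[k] for k in self._ORDER if k in self.boundaries]
        if len(depths) < 2:
            raise ValueError("need at least two layer boundaries")
        arr = np.asarray(depths)
        if (arr <= 0).any() or (np.diff(arr) <= 0).any():
            raise ValueError("boundary depths must be positive and increasing")
        if self.soma_depth is not None and not (
            0 < self.soma_depth < max(depths)
        ):
            raise ValueError("soma_depth must lie between pia and deepest boundary")

    def depth_of(self, y: np.ndarray | float):
        """Cortical depth (um below pia) of a y coordinate."""
        return self.pia_y - np.asarray(y, dtype=float)

    def layer_intervals(self) -> list[tuple[str, float, float]]:
        """(label, top_depth, bottom_depth) per annotated layer, pia first."""
        names = [k for k in self._ORDER if k in self.boundaries]
        edges = [0.0] + [self.boundaries[k] for k in names]
        # canonical labels: the interval above boundary "La/b" is layer La
        labels = []
        for i, k in enumerate(names):
            if k == "wm":
                above = names[i - 1] if i else "pia"
                labels.append("L" + above.split("/")[-1] if above != "pia" else "L1")
            elif k == "L3/4" and "L2/3" not in self.boundaries and i > 0:
                labels.append("L2/3")  # combined layer when L2/3 is unannotated
            else:
                labels.append(k.split("/")[0])
        return [
            (labels[i], edges[i], edges[i + 1]) for i in range(len(names))
        ]


def read_swc(path) -> Morphology:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed SWC line: {line!r}")
            rows.append(
                [
                    int(parts[0]),
                    int(parts[1]),
                    float(parts[2]),
                    float(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    int(parts[6]),
                ]
            )
    if not rows:
        raise ValueError("empty SWC file")
    return Morphology(pd.DataFrame(rows, columns=SWC_COLUMNS))


def write_swc(m: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for row in m.nodes.itertuples(index=False):
            fh.write(
                f"{row.id} {row.type} {row.x:.6f} {row.y:.6f} {row.z:.6f} "
                f"{row.radius:.6f} {row.parent}\n"
            )


def correct_shrinkage(
    m: Morphology, depth_recorded: float, depth_fixed: float
) -> Morphology:
    """Expand z about the soma by the recorded/fixed depth ratio."""
    if depth_recorded <= 0 or depth_fixed <= 0:
        raise ValueError("depths must be positive")
    factor = depth_recorded / depth_fixed
    soma_z = m.soma["z"]
    df = m.nodes.copy()
    df["z"] = soma_z + (df["z"] - soma_z) * factor
    return Morphology(df)


def correct_tilt(m: Morphology, tilt_angle: float) -> Morphology:
    """Rigid rotation about the soma in the y-z (pia-axis / slice-normal) plane."""
    if not abs(tilt_angle) < 90:
        raise ValueError("tilt angle must satisfy |angle| < 90 degrees")
    theta = np.deg2rad(tilt_angle)
    c, s = np.cos(theta), np.sin(theta)
    soma = m.soma
    df = m.nodes.copy()
    dy = df["y"] - soma["y"]
    dz = df["z"] - soma["z"]
    df["y"] = soma["y"] + c * dy - s * dz
    df["z"] = soma["z"] + s * dy + c * dz
    return Morphology(df)


def _check_aligned(m: Morphology, ctx: LayerContext) -> None:
    soma_depth = float(ctx.depth_of(m.soma["y"]))
    bottom = max(ctx.boundaries.values())
    if not (0 <= soma_depth <= bottom):
        raise ValueError(
            f"morphology not aligned to layer context (soma depth {soma_depth:.1f})"
        )


def laminar_histogram(
    m: Morphology,
    compartment: str,
    ctx: LayerContext,
    bin_um: float = 50.0,
):
    """Branch length by cortical depth bin, plus per-layer totals.

    Each inter-node segment's length is apportioned to depth bins in
    proportion to the vertical overlap of the segment with each bin (linear
    interpolation of its endpoints); a depth-constant segment is assigned
    entirely to the bin containing it.  The bin sum equals the compartment's
    total length.

    Returns
    -------
    (bin_edges, bin_lengths, layer_totals) where bin_edges are depths in um
    (increasing, starting at the pia or the shallowest node) and layer_totals
    maps layer labels to lengths with depths clipped into the annotated range.
    """
    comp_types = {"basal": (BASAL,), "apical": (APICAL,), "axon": (AXON,)}
    if compartment not in comp_types:
        raise ValueError(f"unknown compartment {compartment!r}")
    _check_aligned(m, ctx)
    segs = m.segments(*comp_types[compartment])
    d0 = ctx.depth_of(segs["y0"].to_numpy())
    d1 = ctx.depth_of(segs["y1"].to_numpy())
    lengths = segs["length"].to_numpy()

    bottom = max(ctx.boundaries.values())
    lo = min(0.0, d0.min(initial=0.0), d1.min(initial=0.0))
    hi = max(bottom, d0.max(initial=bottom), d1.max(initial=bottom))
    start = np.floor(lo / bin_um) * bin_um
    n_bins = int(np.ceil((hi - start) / bin_um)) or 1
    edges = start + bin_um * np.arange(n_bins + 1)
    bins = np.zeros(n_bins)
    _apportion(bins, edges, d0, d1, lengths)

    intervals = ctx.layer_intervals()
    layer_edges = np.array([intervals[0][1]] + [b for _, _, b in intervals])
    layer_bins = np.zeros(len(intervals))
    dc0 = np.clip(d0, layer_edges[0], layer_edges[-1])
    dc1 = np.clip(d1, layer_edges[0], layer_edges[-1])
    # clipping may collapse a segment; keep its full length in the clipped bin
    _apportion(layer_bins, layer_edges, dc0, dc1, lengths)
    layer_totals = {lab: layer_bins[i] for i, (lab, _, _) in enumerate(intervals)}
    return edges, bins, layer_totals


def _apportion(out, edges, d0, d1, lengths) -> None:
    """Accumulate segment lengths into depth bins by vertical overlap."""
    lo = np.minimum(d0, d1)
    hi = np.maximum(d0, d1)
    span = hi - lo
    flat = span <= 0
    if flat.any():
        idx = np.clip(np.searchsorted(edges, lo[flat], side="right") - 1, 0, len(out) - 1)
        np.add.at(out, idx, lengths[flat])
    sl = ~flat
    if sl.any():
        lo_s, hi_s, len_s, span_s = lo[sl], hi[sl], lengths[sl], span[sl]
        for k in range(len(out)):
            a, b = edges[k], edges[k + 1]
            overlap = np.clip(np.minimum(hi_s, b) - np.maximum(lo_s, a), 0.0, None)
            out[k] += np.sum(len_s * overlap / span_s)


def apical_hist_pc0(layer_fractions: pd.DataFrame) -> pd.Series:
    """First-principal-axis score of per-cell layer-normalized apical histograms.

    ``layer_fractions`` is cells x layers with rows summing to 1.  The sign is
    fixed so that a higher score means more apical length in the shallowest
    (L1) layer.  All-identical histograms yield all-zero scores.
    """
    if len(layer_fractions) < 3:
        raise ValueError("need at least 3 cells")
    X = layer_fractions.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        return pd.Series(np.zeros(len(X)), index=layer_fractions.index)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loading = vt[0]
    scores = Xc @ loading
    l1_col = 0
    if "L1" in layer_fractions.columns:
        l1_col = list(layer_fractions.columns).index("L1")
    if loading[l1_col] < 0:
        scores = -scores
    return pd.Series(scores, index=layer_fractions.index)


def _branch_orders(m: Morphology) -> pd.Series:
    """Branch order per node: soma-emanating stem = 1, +1 at bifurcations."""
    df = m.nodes
    children = df.groupby("parent").size()
    order: dict[int, int] = {}
    type_of = dict(zip(df["id"], df["type"]))
    parent_of = dict(zip(df["id"], df["parent"]))
    for nid in df["id"]:
        p = parent_of[nid]
        if p == -1:
            order[nid] = 0
        elif type_of[p] == SOMA:
            order[nid] = 1
        else:
            bump = 1 if children.get(p, 0) >= 2 else 0
            order[nid] = order[p] + bump
    return pd.Series(order)


def morphometrics(m: Morphology, ctx: LayerContext, include_axon: bool = False) -> dict:
    """Scalar morphometric features (dendrites only unless requested).

    Features dominated by the z dimension are intentionally not computed.
    Missing compartments yield NaN features rather than errors.
    """
    _check_aligned(m, ctx)
    soma = m.soma
    out: dict[str, float] = {"soma_radius": float(soma["radius"])}
    dend_types = [BASAL, APICAL] + ([AXON] if include_axon else [])

    segs = m.segments(BASAL, APICAL)
    out["total_length"] = float(segs["length"].sum()) if len(segs) else np.nan
    for name, t in (("apical", APICAL), ("basal", BASAL)):
        s = m.segments(t)
        out[f"{name}_total_length"] = float(s["length"].sum()) if len(s) else np.nan

    apical = m.of_type(APICAL)
    if len(apical):
        out["apical_height"] = float(apical["y"].max() - apical["y"].min())
        out["apical_depth_bias"] = float(
            ctx.depth_of(soma["y"]) - ctx.depth_of(apical["y"]).mean()
        )
    else:
        out["apical_height"] = np.nan
        out["apical_depth_bias"] = np.nan

    basal = m.of_type(BASAL)
    if len(basal):
        d = np.sqrt(
            (basal["x"] - soma["x"]) ** 2
            + (basal["y"] - soma["y"]) ** 2
            + (basal["z"] - soma["z"]) ** 2
        )
        out["basal_max_distance"] = float(d.max())
        out["basal_max_path_distance"] = float(_max_path_distance(m, BASAL))
    else:
        out["basal_max_distance"] = np.nan
        out["basal_max_path_distance"] = np.nan

    dend = m.of_type(*dend_types)
    if len(dend):
        out["tangential_width"] = float(dend["x"].max() - dend["x"].min())
        orders = _branch_orders(m)
        mask = m.nodes["type"].isin(dend_types).to_numpy()
        out["max_branch_order"] = float(orders.to_numpy()[mask].max())
    else:
        out["tangential_width"] = np.nan
        out["max_branch_order"] = np.nan
    return out


def _max_path_distance(m: Morphology, node_type: int) -> float:
    df = m.nodes
    idx = df.set_index("id")
    dist: dict[int, float] = {}
    best = 0.0
    for row in df.itertuples(index=False):
        if row.parent == -1:
            dist[row.id] = 0.0
            continue
        p = idx.loc[row.parent]
        step = float(
            np.sqrt((row.x - p["x"]) ** 2 + (row.y - p["y"]) ** 2 + (row.z - p["z"]) ** 2)
        )
        base = dist.get(row.parent, 0.0) if p["type"] != SOMA else 0.0
        dist[row.id] = base + step if row.type == node_type else 0.0
        if row.type == node_type:
            best = max(best, dist[row.id])
    return best
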