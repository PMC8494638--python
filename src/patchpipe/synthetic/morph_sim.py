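"""Constructive morphology generator with known laminar ground truth.

Archetypes are parameter presets that contrast qualitatively:

``superficial``
    apical trunk crosses the L1/2 boundary and tufts inside L1;
``deep-col22a1-like``
    apical trunk terminates below the L1/2 boundary (zero apical length in
    L1) and carries a wider basal field.

Coordinates are pia-aligned (``y = pia_y - depth``).  The returned ground
truth (apical vertical extent, basal maximum Euclidean distance, apical L1
length fraction) is measured on the generated node table itself by direct
scans, so downstream feature extractors can be tested for exact recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..morph_features import (
    APICAL,
    AXON,
    BASAL,
    SOMA,
    LayerContext,
    Morphology,
)

__all__ = ["ARCHETYPES", "simulate_morphology"]

ARCHETYPES = {
    "superficial": dict(
        n_basal=5,
        basal_extent=220.0,
        n_tuft=3,
        tuft_length=80.0,
        n_oblique=3,
        oblique_length=120.0,
    ),
    "deep-col22a1-like": dict(
        n_basal=6,
        basal_extent=320.0,
        n_tuft=2,
        tuft_length=60.0,
        n_oblique=4,
        oblique_length=150.0,
    ),
}

_NODE_STEP = 20.0  # um between consecutive nodes on a neurite


class _Builder:
    def __init__(self) -> None:
        self.rows: list[list] = []

    def add(self, ntype, x, y, z, radius, parent) -> int:
        nid = len(self.rows) + 1
        self.rows.append([nid, ntype, float(x), float(y), float(z), radius, parent])
        return nid

    def chain(self, ntype, start_id, p0, direction, length, radius) -> int:
        """Straight run of nodes from p0 (exclusive) along a unit direction."""
        n_steps = max(1, int(round(length / _NODE_STEP)))
        parent = start_id
        p = np.asarray(p0, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        for k in range(1, n_steps + 1):
            q = p + d * (length * k / n_steps)
            parent = self.add(ntype, q[0], q[1], q[2], radius, parent)
        return parent

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["id", "type", "x", "y", "z", "radius", "parent"]
        )


def simulate_morphology(
    archetype: str,
    soma_depth: float,
    layer_context: LayerContext,
    seed: int = 0,
) -> tuple[Morphology, dict]:
    """Generate a typed node tree; returns (morphology, ground_truth)."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; options: {sorted(ARCHETYPES)}")
    ctx = layer_context
    l12 = ctx.boundaries["L1/2"]
    l34 = ctx.boundaries["L3/4"]
    if not (l12 < soma_depth < l34):
        raise ValueError(
            f"soma depth {soma_depth} outside L2-L3 ({l12}-{l34}) of the layer context"
        )
    p = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    b = _Builder()

    soma_y = ctx.pia_y - soma_depth
    soma_id = b.add(SOMA, 0.0, soma_y, 0.0, 6.0, -1)

    # apical trunk straight toward the pia
    if archetype == "superficial":
        tip_depth = 0.45 * l12  # mid-L1
    else:
        # terminates below the L1/2 boundary, whatever the soma depth
        tip_depth = min(l12 + 60.0, soma_depth - _NODE_STEP)
        if tip_depth <= l12:
            tip_depth = (l12 + soma_depth) / 2.0
    trunk_len = soma_depth - tip_depth
    trunk_end = b.chain(APICAL, soma_id, (0.0, soma_y, 0.0), (0, 1, 0), trunk_len, 1.5)

    # tuft branches at the trunk tip
    tip = np.array([0.0, ctx.pia_y - tip_depth, 0.0])
    for k in range(p["n_tuft"]):
        ang = rng.uniform(0, 2 * np.pi)
        elev = rng.uniform(0.3, 0.7)
        d = np.array([np.cos(ang) * (1 - elev), elev, np.sin(ang) * (1 - elev)])
        tl = p["tuft_length"] * rng.uniform(0.7, 1.0)
        if archetype != "superficial":
            # horizontal tuft keeps the deep archetype strictly below L1/2
            d = np.array([np.cos(ang), 0.0, np.sin(ang)])
        b.chain(APICAL, trunk_end, tip, d, tl, 1.0)

    # oblique branches off the trunk
    for k in range(p["n_oblique"]):
        frac = rng.uniform(0.2, 0.8)
        branch_depth = soma_depth - frac * trunk_len
        # attach to the nearest existing trunk node
        trunk_nodes = [r for r in b.rows if r[1] == APICAL and r[0] <= trunk_end]
        ys = np.array([r[3] for r in trunk_nodes])
        j = int(np.argmin(np.abs(ys - (ctx.pia_y - branch_depth))))
        anchor = trunk_nodes[j]
        ang = rng.uniform(0, 2 * np.pi)
        d = np.array([np.cos(ang), 0.1, np.sin(ang)])
        b.chain(
            APICAL,
            anchor[0],
            (anchor[2], anchor[3], anchor[4]),
            d,
            p["oblique_length"] * rng.uniform(0.6, 1.0),
            1.0,
        )

    # basal subtrees radiating from the soma, with one bifurcation midway
    for k in range(p["n_basal"]):
        ang = 2 * np.pi * k / p["n_basal"] + rng.uniform(-0.2, 0.2)
        elev = rng.uniform(-0.35, 0.05)
        d = np.array([np.cos(ang), elev, np.sin(ang)])
        d /= np.linalg.norm(d)
        ext = p["basal_extent"] * rng.uniform(0.6, 1.0)
        half = ext / 2
        mid = b.chain(BASAL, soma_id, (0.0, soma_y, 0.0), d, half, 1.2)
        mid_pos = np.array(b.rows[mid - 1][2:5])
        for sgn in (-1, 1):
            dd = d + sgn * 0.35 * np.array([-d[2], 0.0, d[0]])
            b.chain(BASAL, mid, mid_pos, dd, half, 1.0)

    # descending axon stub
    b.chain(AXON, soma_id, (0.0, soma_y, 0.0), (0.05, -1.0, 0.0), 400.0, 0.5)

    df = b.frame()
    m = Morphology(df)

    # ground truth by direct scans of the generated node table
    apical = df[df["type"] == APICAL]
    basal = df[df["type"] == BASAL]
    bd = np.sqrt(
        (basal["x"] - 0.0) ** 2 + (basal["y"] - soma_y) ** 2 + basal["z"] ** 2
    )
    truth = {
        "archetype": archetype,
        "soma_depth_um": soma_depth,
        "apical_vertical_extent_um": float(apical["y"].max() - apical["y"].min()),
        "basal_max_distance_um": float(bd.max()),
        "apical_l1_fraction": _l1_fraction(df, ctx),
    }
    return m, truth


def _l1_fraction(df: pd.DataFrame, ctx: LayerContext) -> float:
    """Fraction of apical length above the L1/2 boundary (exact segment clip)."""
    l12_y = ctx.pia_y - ctx.boundaries["L1/2"]
    idx = df.set_index("id")
    total = 0.0
    in_l1 = 0.0
    for row in df.itertuples(index=False):
        if row.type != APICAL or row.parent == -1:
            continue
        par = idx.loc[row.parent]
        seg = np.array([row.x - par["x"], row.y - par["y"], row.z - par["z"]])
        length = float(np.linalg.norm(seg))
        total += length
        y0, y1 = sorted((par["y"], row.y))
        if y1 <= l12_y:
            continue
        if y0 >= l12_y:
            in_l1 += length
        else:
            in_l1 += length * (y1 - l12_y) / (y1 - y0)
    return in_l1 / total if total else 0.0
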