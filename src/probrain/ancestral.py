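"""Maximum-likelihood ancestral state reconstruction under Brownian motion.

For each internal node v the ML estimate of the ancestral state equals the
GLS phylogenetic mean computed with the tree re-rooted at v:

    a_v = (1' C_v^-1 1)^-1 1' C_v^-1 y,

where C_v is the tip covariance of the re-rooted tree.  Re-rooting is done
implicitly through unrooted path lengths: C_v[i, j] =
(d(v,i) + d(v,j) - d(i,j)) / 2.  Estimation variances are
sigma2_ML * (1' C_v^-1 1)^-1 with sigma2_ML the Brownian rate estimated at
the root; 95% intervals are estimate +/- 1.96 * sqrt(variance).

Brain and body mass are reconstructed on the log10 scale (they span five
orders of magnitude across the dataset) and back-transformed for reporting;
the encephalization quotient is reconstructed on the linear scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treedata import CalibratedTree, SpecimenTable

log = logging.getLogger(__name__)

__all__ = [
    "AncestralStates",
    "ml_ancestral_states",
    "reconstruct_traits",
    "node_change_summary",
    "PULSE_THRESHOLD",
]

#: EQ parent-to-child ratio above which an edge is flagged as a pulse
#: ("doubling or near-doubling" of relative brain size).
PULSE_THRESHOLD = 1.4

_MIN_BRANCH = 1e-8  # flooring applied inside the solver only
_Z95 = 1.959963984540054


@dataclass
class AncestralStates:
    """Per-internal-node ML estimates for one trait.

    ``scale`` records the reconstruction scale ("linear" or "log10"); the
    estimates/variances/intervals are on that scale.  ``linear_estimate``
    back-transforms log10 reconstructions (no bias correction).
    """

    trait: str
    scale: str
    node_ids: np.ndarray          # internal node ids of the tree
    node_labels: list[str | None]
    estimates: np.ndarray
    variances: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sigma2: float                 # ML Brownian rate on the reconstruction scale

    def __post_init__(self) -> None:
        if np.any(self.variances < -1e-12):
            raise ValueError("negative estimation variance")
        self.variances = np.maximum(self.variances, 0.0)

    def estimate_at(self, node_label: str) -> float:
        for i, lab in enumerate(self.node_labels):
            if lab == node_label:
                return float(self.estimates[i])
        raise KeyError(f"no internal node labelled {node_label!r}")

    @property
    def root_estimate(self) -> float:
        return float(self.estimates[0])

    @property
    def linear_estimates(self) -> np.ndarray:
        return 10.0 ** self.estimates if self.scale == "log10" else self.estimates

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "node": self.node_ids,
            "clade": self.node_labels,
            "trait": self.trait,
            "scale": self.scale,
            "estimate": self.estimates,
            "variance": self.variances,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })
        df["estimate_linear"] = self.linear_estimates
        return df


def _floored_tree(tree: CalibratedTree) -> CalibratedTree:
    if np.any(tree.blen[1:] < _MIN_BRANCH):
        n_floored = int(np.sum(tree.blen[1:] < _MIN_BRANCH))
        log.warning("flooring %d branch lengths to %g Ma inside the reconstruction solver",
                    n_floored, _MIN_BRANCH)
        out = tree.copy()
        out.blen[1:] = np.maximum(out.blen[1:], _MIN_BRANCH)
        return out
    return tree


def ml_ancestral_states(tree: CalibratedTree, tip_values, trait: str = "trait",
                        scale: str = "linear") -> AncestralStates:
    """Reconstruct every internal node of ``tree`` for one continuous trait.

    ``tip_values`` maps tip label -> value (a Mapping or pandas Series); a
    missing tip raises.  The root estimate equals the GLS phylogenetic mean
    of the tips; all node estimates jointly maximize the Brownian likelihood.
    """
    tip_values = dict(tip_values)
    missing = [t for t in tree.tip_labels if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    work = _floored_tree(tree)
    tips = work.tips
    labels = [work.labels[v] for v in tips]
    y = np.array([float(tip_values[lab]) for lab in labels])
    n = len(y)

    # tip-tip and node-tip path lengths on the (floored) tree
    D_nt = work.node_tip_distances()          # (n_nodes, n_tips)
    S, _ = work.shared_path_matrix(labels)    # root-to-MRCA shared paths
    depths = np.diag(S)
    D_tt = depths[:, None] + depths[None, :] - 2.0 * S

    internal = work.internal_nodes
    est = np.empty(len(internal))
    var = np.empty(len(internal))
    ones = np.ones(n)
    sigma2 = np.nan
    for k, v in enumerate(internal):
        dv = D_nt[v]
        Cv = 0.5 * (dv[:, None] + dv[None, :] - D_tt)
        w = np.linalg.solve(Cv, ones)
        denom = float(w @ ones)
        a_v = float(w @ y) / denom
        est[k] = a_v
        var[k] = 1.0 / denom
        if v == 0:  # root: ML Brownian rate from the rooted covariance
            e = y - a_v
            sigma2 = float(e @ np.linalg.solve(Cv, e)) / n
    var *= sigma2
    half = _Z95 * np.sqrt(var)
    return AncestralStates(
        trait=trait,
        scale=scale,
        node_ids=np.array(internal),
        node_labels=[tree.labels[v] for v in internal],
        estimates=est,
        variances=var,
        ci_low=est - half,
        ci_high=est + half,
        sigma2=sigma2,
    )


def reconstruct_traits(tree: CalibratedTree, table: SpecimenTable,
                       traits=("brain", "body", "eq")) -> dict[str, AncestralStates]:
    """Independent reconstructions of brain mass, body mass and EQ.

    Tip values come from the proboscidean specimen rows (printed columns,
    falling back to the recomputed ones from
    :func:`probrain.allometry.compute_eq_table` when a printed value is
    absent).  Masses are reconstructed on log10, EQ on the linear scale.
    """
    df = table.df[table.df["group"] == "proboscidean"].set_index("specimen_id")

    def column(printed: str, recomputed: str) -> pd.Series:
        vals = df[printed] if printed in df else pd.Series(np.nan, index=df.index)
        if recomputed in df:
            vals = vals.fillna(df[recomputed])
        if vals.isna().any():
            raise ValueError(f"missing {printed} for: {sorted(vals[vals.isna()].index)}")
        return vals.astype(float)

    sources = {
        "brain": ("log10", np.log10(column("brain_g", "brain_g_recomputed"))),
        "body": ("log10", np.log10(column("body_g", "body_g"))),
        "eq": ("linear", column("eq", "eq_recomputed")),
    }
    out = {}
    for name in traits:
        scale, values = sources[name]
        out[name] = ml_ancestral_states(tree, values, trait=name, scale=scale)
    return out


def node_change_summary(states: dict[str, AncestralStates], tree: CalibratedTree,
                        pulse_threshold: float = PULSE_THRESHOLD) -> pd.DataFrame:
    """Parent-to-child ratios of reconstructed traits along internal edges.

    Ratios are on the linear scale.  An edge is flagged a pulse of relative
    brain-size increase when the EQ ratio reaches ``pulse_threshold`` while
    body mass grows by a smaller factor than EQ (brain outpacing body).
    """
    ref = next(iter(states.values()))
    idx = {int(v): i for i, v in enumerate(ref.node_ids)}
    for s in states.values():
        if list(s.node_ids) != list(ref.node_ids):
            raise ValueError("reconstructions do not share the tree")
    rows = []
    for v in ref.node_ids[1:]:
        u = int(tree.parent[int(v)])
        if u not in idx:
            continue
        row = {
            "parent": u, "child": int(v),
            "parent_clade": tree.labels[u], "child_clade": tree.labels[int(v)],
            "edge_length_ma": float(tree.blen[int(v)]),
        }
        for name, s in states.items():
            lin = s.linear_estimates
            row[f"{name}_ratio"] = float(lin[idx[int(v)]] / lin[idx[u]])
        if "eq" in states and "body" in states:
            row["pulse"] = bool(row["eq_ratio"] >= pulse_threshold
                                and row["body_ratio"] < row["eq_ratio"])
        rows.append(row)
    return pd.DataFrame(rows)
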