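"""Core-TF identification, Kd-ratio reports and regulatory digraph export.

A core TF is one whose fitted dissociation constant moved away from its
initial value during optimization — the network cannot reproduce the
reference expression while that TF keeps its prior affinity, implicating
it as a driver.  Comparing a condition fit against a control fit gives
per-TF Kd ratios: a high ratio (weakened binding) reads as inhibition of
that TF in the condition, a low ratio as activation.

Digraphs are built from the derivative-factor matrices: an edge
regulator -> target exists wherever the sensitivity of the target's
activation (or repression) term to the regulator is nonzero.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .fitting import TRNFitResult

DEFAULT_TOLERANCE = 0.5  # log10 units, ~3.2-fold Kd change
_ZERO_DENOM = 1e-12


def core_tfs(fit: TRNFitResult, tolerance: float = DEFAULT_TOLERANCE) -> list[str]:
    """TFs whose |log10(kd_final / kd_init)| exceeds ``tolerance``.

    Clamped TFs are excluded (their Kd was held, not learned).  Sorted by
    magnitude of change, descending.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    change = fit.log10_kd_change.abs()
    eligible = change[~fit.fixed_mask]
    hits = eligible[eligible > tolerance]
    return list(hits.sort_values(ascending=False).index)


@dataclass
class CoreTFReport:
    """Condition-vs-control Kd comparison."""

    core_set: list[str]
    kd_ratio: pd.Series  # condition kd_final / control kd_final
    log2_ratio: pd.Series
    clamped: list[str]
    tolerance: float

    @property
    def most_inhibited(self) -> str:
        """TF with the largest ratio: higher Kd = weaker binding = inhibition."""
        return self.kd_ratio.drop(self.clamped, errors="ignore").idxmax()

    @property
    def most_activated(self) -> str:
        return self.kd_ratio.drop(self.clamped, errors="ignore").idxmin()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "kd_ratio": self.kd_ratio,
                "log2_ratio": self.log2_ratio,
                "clamped": [t in self.clamped for t in self.kd_ratio.index],
                "core": [t in self.core_set for t in self.kd_ratio.index],
            }
        )
        df.index.name = "tf_id"
        return df


def kd_ratio_report(
    fit_condition: TRNFitResult,
    fit_control: TRNFitResult,
    tolerance: float = DEFAULT_TOLERANCE,
) -> CoreTFReport:
    """Per-TF ratio of fitted Kd between a condition fit and its control.

    Both fits must share the TF roster.  TFs clamped in either fit are
    flagged and excluded from the inhibition/activation ranking.
    """
    roster_c = list(fit_condition.kd_final.index)
    roster_k = list(fit_control.kd_final.index)
    if roster_c != roster_k:
        diff = sorted(set(roster_c).symmetric_difference(roster_k))
        raise ValueError(f"TF roster mismatch between fits: {diff}")
    ratio = fit_condition.kd_final / fit_control.kd_final
    clamped = sorted(
        set(fit_condition.fixed_mask.index[fit_condition.fixed_mask])
        | set(fit_control.fixed_mask.index[fit_control.fixed_mask])
    )
    core = [t for t in core_tfs(fit_condition, tolerance) if t not in clamped]
    return CoreTFReport(
        core_set=core,
        kd_ratio=ratio,
        log2_ratio=np.log2(ratio),
        clamped=clamped,
        tolerance=tolerance,
    )


@dataclass
class DigraphEdgeSet:
    """Signed weighted edges regulator -> target with degree summaries."""

    edges: list[tuple[str, str, float, str]]  # (source, target, weight, sign)
    mode: str

    def graph(self) -> nx.MultiDiGraph:
        # multigraph: a regulator may hit the same target through both the
        # promoter (activating) and the gene body (repressive)
        g = nx.MultiDiGraph()
        for src, tgt, w, sign in self.edges:
            g.add_edge(src, tgt, weight=float(w), sign=sign)
        return g

    def in_degree_ranking(self) -> pd.Series:
        """Nodes ranked by in-degree; higher in-degree = more central position."""
        g = self.graph()
        deg = pd.Series(dict(g.in_degree()), dtype=int)
        return deg.sort_values(ascending=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "weight", "sign"])


def build_digraph(
    A_matrix: pd.DataFrame,
    R_matrix: pd.DataFrame,
    mode: str = "absolute",
    A_control: Optional[pd.DataFrame] = None,
    R_control: Optional[pd.DataFrame] = None,
) -> DigraphEdgeSet:
    """Edge set from derivative-factor matrices.

    ``absolute`` mode: one edge per nonzero entry, weight = derivative
    factor, sign "activating" for promoter (A) entries and "repressive"
    for gene-body (R) entries.  ``condition_over_control`` mode: weight =
    condition / control entry; entries whose control value is ~0 are
    dropped with a warning.
    """
    if mode not in ("absolute", "condition_over_control"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = [(A_matrix, A_control, "activating"), (R_matrix, R_control, "repressive")]
    edges: list[tuple[str, str, float, str]] = []
    dropped = 0
    for mat, ctrl, sign in pairs:
        if mode == "condition_over_control":
            if ctrl is None or ctrl.shape != mat.shape:
                raise ValueError(f"{sign} control matrix missing or shape mismatch")
        for src in mat.index:
            row = mat.loc[src]
            for tgt in mat.columns[row.to_numpy() != 0]:
                w = float(mat.loc[src, tgt])
                if mode == "condition_over_control":
                    c = float(ctrl.loc[src, tgt])
                    if abs(c) <= _ZERO_DENOM:
                        dropped += 1
                        continue
                    w = w / c
                edges.append((src, tgt, w, sign))
    if dropped:
        warnings.warn(f"dropped {dropped} ratio edges with ~zero control values")
    return DigraphEdgeSet(edges=edges, mode=mode)


def export_digraph(edge_set: DigraphEdgeSet, out_dir: str) -> None:
    """Write Act_list.csv / Rep_list.csv and a GraphML file."""
    os.makedirs(out_dir, exist_ok=True)
    df = edge_set.to_frame()
    for sign, name in (("activating", "Act_list.csv"), ("repressive", "Rep_list.csv")):
        sub = df[df["sign"] == sign].copy()
        sub["mode"] = edge_set.mode
        sub.to_csv(os.path.join(out_dir, name), index=False, float_format="%.12g")
    nx.write_graphml(edge_set.graph(), os.path.join(out_dir, "network.graphml"))


def read_edge_lists(out_dir: str, mode: str = "absolute") -> DigraphEdgeSet:
    """Round-trip reader for the Act_/Rep_list.csv pair."""
    edges = []
    for name in ("Act_list.csv", "Rep_list.csv"):
        df = pd.read_csv(os.path.join(out_dir, name))
        for rec in df.itertuples(index=False):
            edges.append((rec.source, rec.target, float(rec.weight), rec.sign))
    return DigraphEdgeSet(edges=edges, mode=mode)


def write_core_report(
    fit: TRNFitResult, out_dir: str, tolerance: float = DEFAULT_TOLERANCE
) -> pd.DataFrame:
    """core_tfs.csv (tf_id, kd_init, kd_final, log10_change) + report.json."""
    import json

    os.makedirs(out_dir, exist_ok=True)
    core = core_tfs(fit, tolerance)
    df = pd.DataFrame(
        {
            "tf_id": fit.kd_final.index,
            "kd_init": fit.kd_init.values,
            "kd_final": fit.kd_final.values,
            "log10_change": fit.log10_kd_change.values,
            "clamped": fit.fixed_mask.values,
            "core": [t in core for t in fit.kd_final.index],
        }
    )
    df.to_csv(os.path.join(out_dir, "core_tfs.csv"), index=False, float_format="%.12g")
    summary = {
        "n_tfs": int(len(fit.kd_final)),
        "n_core": int(len(core)),
        "core_tfs": core,
        "tolerance_log10": tolerance,
        "final_loss": float(fit.loss_trajectory[-1]),
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return df
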