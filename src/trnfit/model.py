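"""Thermodynamic forward model of the TF regulatory network.

Each gene's transcription rate is driven by the equilibrium occupancy of
up to four binding sites in its open promoter.  A site with normalized
motif score Sp contributes with weight 10^(-a(1-Sp)); for an activator at
concentration [A] with dissociation constant Kd, competing against its
strongest repressor R (score Sq, inhibition constant Ki), the expected
occupancy of a gene's sites is

    r = sum_p  w_p [A] / (Kd + w_p [A] + w_q (Kd/Ki) [R]),   w = 10^(-a(1-S))

and the transcription flux contributed by that activator is kc * exp(-1/r).
Promoters whose summed top-4 scores exceed a threshold switch to a
cooperative (Hill-like) occupancy, modelling super-enhancer behaviour.
TFs bound within the gene body repress: their flux is subtracted, as is
the flux of TFs annotated repressor-only; negative totals clamp to zero.

Protein loss follows Michaelis-Menten kinetics; its exact one-step
solution is g(x) = W(exp(x + log x - d)) with W the Lambert W function
(evaluated via the Wright omega function for numerical range).  One update
step of TF concentration x_m is then  x' = f(x) + g(x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import wrightomega

from .motifs import BindingSite

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ModelParams:
    """Global model parameters.

    a: exponential weighting of motif-score mismatch (dimensionless, > 0).
       Higher a makes binding more consensus-selective.
    kc: basal transcription constant (expression units per step); absorbs
        RNA-polymerase concentration, chromatin constant and RT.
    d: degradation rate of nuclear protein per step (>= 0).
    se_threshold: sum of top-4 Sp scores above which a promoter-TF pair is
        treated as a cooperative super-enhancer.
    p_max: maximum number of binding sites per (region, TF); fixed at 4.
    """

    a: float = 10.0
    kc: float = 1.0
    d: float = 0.5
    se_threshold: float = 3.0
    p_max: int = 4

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.kc <= 0:
            raise ValueError("kc must be > 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.p_max != 4:
            raise ValueError("p_max is fixed at 4")


@dataclass
class KdVector:
    """Per-TF dissociation constants (kd), inhibition constants (ki) and clamps."""

    tfs: list[str]
    kd: np.ndarray
    ki: np.ndarray
    fixed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.kd = np.asarray(self.kd, dtype=float)
        self.ki = np.asarray(self.ki, dtype=float)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        if (self.kd <= 0).any() or (self.ki <= 0).any():
            raise ValueError("kd and ki must be strictly positive")

    @classmethod
    def uniform(
        cls,
        tfs: Sequence[str],
        kd: float = 1.0,
        ki: Optional[Mapping[str, float]] = None,
    ) -> "KdVector":
        kd_arr = np.full(len(tfs), float(kd))
        ki_arr = kd_arr.copy() if ki is None else np.array([ki.get(t, kd) for t in tfs])
        return cls(list(tfs), kd_arr, ki_arr, np.zeros(len(tfs), dtype=bool))

    def as_series(self) -> pd.Series:
        return pd.Series(self.kd, index=self.tfs, name="kd")


# ---------------------------------------------------------------------------
# elementary kinetics


def site_weight(sp: ArrayLike, a: float) -> ArrayLike:
    """Exponential weight 10^(-a(1-Sp)) of a site with score Sp in [0, 1]."""
    sp_arr = np.asarray(sp, dtype=float)
    if a <= 0:
        raise ValueError("a must be > 0")
    if np.any(sp_arr < 0) or np.any(sp_arr > 1):
        raise ValueError("sp must lie in [0, 1]")
    out = 10.0 ** (-a * (1.0 - sp_arr))
    return float(out) if np.isscalar(sp) else out


def degrade(x: ArrayLike, d: float) -> ArrayLike:
    """Residual concentration after one time unit of Michaelis-Menten decay.

    Exact solution of dx/dt = -d x / (1 + x) over unit time:
    g(x) = W(exp(x + log x - d)), computed as wrightomega(x + log x - d).
    g(0) = 0; d = 0 is the identity.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("x must be >= 0")
    with np.errstate(divide="ignore"):
        z = x_arr + np.log(x_arr) - d
    out = np.real(wrightomega(z))
    out = np.where(x_arr > 0, out, 0.0)
    return float(out) if np.isscalar(x) else out


def activator_contribution(r: ArrayLike, kc: float) -> ArrayLike:
    """Transcription flux kc * exp(-1/r) from occupancy r; continuous 0 at r = 0."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("r must be >= 0")
    safe = np.where(r_arr > 0, r_arr, 1.0)
    out = np.where(r_arr > 0, kc * np.exp(-1.0 / safe), 0.0)
    return float(out) if np.isscalar(r) else out


def occupancy(
    sites: Sequence[BindingSite],
    A: float,
    kd: float,
    ki_map: Mapping[str, float],
    R_conc_map: Mapping[str, float],
    a: float,
    se_threshold: float = 3.0,
) -> float:
    """Expected number of bound activator molecules across a gene's sites.

    Sub-threshold (sum of Sp <= se_threshold): independent saturation per
    site with competitive repression.  Above threshold the cooperative
    super-enhancer form applies: numerator sum_p w_p A^p, denominator
    kd^P + numerator + repressor terms, with P the number of sites.
    """
    if A < 0:
        raise ValueError("A must be >= 0")
    if len(sites) > 4:
        raise ValueError("at most 4 sites per (region, TF)")
    if not sites or A == 0:
        return 0.0
    w = np.array([site_weight(s.sp, a) for s in sites])
    rep = np.zeros(len(sites))
    for i, s in enumerate(sites):
        if s.repressor_id is not None and s.sq is not None:
            ki = float(ki_map.get(s.repressor_id, kd))
            rep[i] = (
                site_weight(s.sq, a) * (kd / ki) * float(R_conc_map.get(s.repressor_id, 0.0))
            )
    sp_sum = sum(s.sp for s in sites)
    if sp_sum <= se_threshold:
        return float(np.sum(w * A / (kd + w * A + rep)))
    p = np.arange(1, len(sites) + 1, dtype=float)
    num = np.sum(w * A**p)
    den = kd ** len(sites) + num + np.sum(rep)
    return float(num / den)


def gene_regulation(
    promoter_sites: Mapping[str, Sequence[BindingSite]],
    body_sites: Mapping[str, Sequence[BindingSite]],
    state: Mapping[str, float],
    kd: Mapping[str, float],
    ki: Mapping[str, float],
    params: ModelParams,
    repressor_only: Iterable[str] = (),
) -> float:
    """Net transcription flux of one gene from its binding profiles.

    Promoter-bound TFs activate (or, when annotated repressor-only,
    subtract with the same functional form); gene-body-bound TFs always
    subtract.  The total clamps at zero.  ``state`` maps TF id to
    concentration.  A reference implementation: the vectorized engine in
    :class:`TRNModel` computes the same quantity.
    """
    rep_only = set(repressor_only)
    flux = 0.0
    for tf_id, sites in promoter_sites.items():
        r = occupancy(
            sites,
            float(state.get(tf_id, 0.0)),
            float(kd[tf_id]),
            ki,
            state,
            params.a,
            params.se_threshold,
        )
        contrib = activator_contribution(r, params.kc)
        flux += -contrib if tf_id in rep_only else contrib
    for tf_id, sites in body_sites.items():
        r = occupancy(
            sites,
            float(state.get(tf_id, 0.0)),
            float(kd[tf_id]),
            ki,
            state,
            params.a,
            params.se_threshold,
        )
        flux -= activator_contribution(r, params.kc)
    return max(flux, 0.0)


# ---------------------------------------------------------------------------
# compiled pairwise design for the vectorized engine


@dataclass
class _PairClass:
    """Flat arrays over (target gene, regulator TF) pairs of one region class."""

    pair_tf: np.ndarray  # (P,) regulator index into tf roster
    tf_col: np.ndarray  # (P,) concentration column of the regulator
    w: np.ndarray  # (P,4) site weights, zero-padded
    rank: np.ndarray  # (P,4) Hill exponents 1..n
    n_sites: np.ndarray  # (P,)
    rep_col: np.ndarray  # (P,4) concentration column of each site's repressor
    rep_tf: np.ndarray  # (P,4) repressor index into tf roster (0 when none; wq=0)
    wq: np.ndarray  # (P,4) repressor weights (kd/ki applied at evaluation)
    se_idx: np.ndarray  # indices of super-enhancer pairs
    signed_M: np.ndarray  # (P,G) scatter matrix carrying the pair sign

    @property
    def n_pairs(self) -> int:
        return self.pair_tf.shape[0]


class TRNModel:
    """TF regulatory network model built from binding profiles.

    Parameters
    ----------
    promoter_profiles, gene_body_profiles : DataFrame
        Interchange tables (gene_id, tf_id, site_rank, offset, strand, sp,
        repressor_id, sq) produced by the motif stage; gene_body_profiles
        may be empty.
    tf_table : DataFrame
        Indexed by tf_id with columns gene_id (the TF's encoding gene) and
        is_repressor_only.
    params : ModelParams, optional

    The gene roster is the sorted set of genes appearing in the promoter
    profiles (genes without an open promoter are outside the network).  A
    TF whose encoding gene is not in the roster acts as a frozen input: its
    concentration stays at the initial value throughout a simulation.
    """

    def __init__(
        self,
        promoter_profiles: pd.DataFrame,
        gene_body_profiles: Optional[pd.DataFrame] = None,
        tf_table: Optional[pd.DataFrame] = None,
        params: Optional[ModelParams] = None,
    ) -> None:
        if tf_table is None:
            raise ValueError("tf_table is required")
        if promoter_profiles.empty:
            raise ValueError("promoter profiles are empty: no genes to model")
        self.params = params or ModelParams()
        self.genes: list[str] = sorted(promoter_profiles["gene_id"].unique())
        self.tfs: list[str] = sorted(tf_table["tf_id"].astype(str))
        self.tf_table = tf_table.loc[self.tfs]
        self._gene_pos = {g: i for i, g in enumerate(self.genes)}
        self._tf_pos = {t: i for i, t in enumerate(self.tfs)}
        self.repressor_only = set(
            self.tf_table.index[self.tf_table["is_repressor_only"]].astype(str)
        )

        # concentration columns: genes, then frozen TFs, then a zero column
        tf_gene = self.tf_table["gene_id"].astype(str)
        self._frozen_tfs = [t for t in self.tfs if tf_gene[t] not in self._gene_pos]
        frozen_pos = {t: len(self.genes) + i for i, t in enumerate(self._frozen_tfs)}
        self._zero_col = len(self.genes) + len(self._frozen_tfs)
        self._tf_conc_col = np.array(
            [
                self._gene_pos[tf_gene[t]] if tf_gene[t] in self._gene_pos else frozen_pos[t]
                for t in self.tfs
            ]
        )
        self._frozen_gene_ids = [tf_gene[t] for t in self._frozen_tfs]

        body = gene_body_profiles if gene_body_profiles is not None else pd.DataFrame(
            columns=promoter_profiles.columns
        )
        self._promoter = self._compile(promoter_profiles, signed=True)
        self._body = self._compile(body, signed=False)
        self.promoter_profiles = promoter_profiles
        self.gene_body_profiles = body

    # -- construction -------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        promoter_csv: str,
        gene_body_csv: Optional[str],
        tf_table_tsv: str,
        params: Optional[ModelParams] = None,
    ) -> "TRNModel":
        from . import io

        body = io.read_profiles(gene_body_csv) if gene_body_csv else None
        return cls(io.read_profiles(promoter_csv), body, io.read_tf_table(tf_table_tsv), params)

    def _compile(self, profiles: pd.DataFrame, signed: bool) -> _PairClass:
        a = self.params.a
        P = 0
        rows: dict[tuple[str, str], list] = {}
        if not profiles.empty:
            known = profiles["tf_id"].isin(self._tf_pos) & profiles["gene_id"].isin(
                self._gene_pos
            )
            profs = profiles.loc[known]
            for rec in profs.itertuples(index=False):
                rows.setdefault((rec.gene_id, rec.tf_id), []).append(rec)
        keys = sorted(rows)
        P = len(keys)
        pair_tf = np.zeros(P, dtype=np.int64)
        pair_gene = np.zeros(P, dtype=np.int64)
        w = np.zeros((P, 4))
        wq = np.zeros((P, 4))
        rep_tf = np.zeros((P, 4), dtype=np.int64)
        rep_col = np.full((P, 4), self._zero_col, dtype=np.int64)
        n_sites = np.zeros(P, dtype=np.int64)
        sp_sum = np.zeros(P)
        for i, key in enumerate(keys):
            gene_id, tf_id = key
            sites = sorted(rows[key], key=lambda r: (-r.sp, r.offset, r.strand))[:4]
            pair_tf[i] = self._tf_pos[tf_id]
            pair_gene[i] = self._gene_pos[gene_id]
            n_sites[i] = len(sites)
            for j, s in enumerate(sites):
                w[i, j] = 10.0 ** (-a * (1.0 - float(s.sp)))
                sp_sum[i] += float(s.sp)
                rid = getattr(s, "repressor_id", "")
                if isinstance(rid, str) and rid and rid in self._tf_pos and not (
                    isinstance(s.sq, float) and np.isnan(s.sq)
                ):
                    wq[i, j] = 10.0 ** (-a * (1.0 - float(s.sq)))
                    rep_tf[i, j] = self._tf_pos[rid]
                    rep_col[i, j] = self._tf_conc_col[self._tf_pos[rid]]
        rank = np.tile(np.arange(1, 5, dtype=float), (P, 1))
        se_idx = np.flatnonzero(sp_sum > self.params.se_threshold)
        sign = np.ones(P)
        if signed:
            for i, (gene_id, tf_id) in enumerate(keys):
                if tf_id in self.repressor_only:
                    sign[i] = -1.0
        signed_M = np.zeros((P, len(self.genes)))
        signed_M[np.arange(P), pair_gene] = sign
        return _PairClass(
            pair_tf=pair_tf,
            tf_col=self._tf_conc_col[pair_tf],
            w=w,
            rank=rank,
            n_sites=n_sites,
            rep_col=rep_col,
            rep_tf=rep_tf,
            wq=wq,
            se_idx=se_idx,
            signed_M=signed_M,
        )

    # -- state handling ------------------------------------------------------

    def _as_state(self, x: Union[pd.Series, np.ndarray, Mapping[str, float]]) -> np.ndarray:
        if isinstance(x, pd.Series):
            missing = [g for g in self.genes if g not in x.index]
            if missing:
                raise ValueError(f"state missing genes: {missing[:5]}")
            arr = x.reindex(self.genes).to_numpy(dtype=float)
        elif isinstance(x, Mapping):
            arr = np.array([float(x[g]) for g in self.genes])
        else:
            arr = np.asarray(x, dtype=float)
            if arr.shape != (len(self.genes),):
                raise ValueError(f"state must have length {len(self.genes)}")
        if (arr < 0).any():
            raise ValueError("state must be non-negative")
        return arr

    def _frozen_from(self, x: Union[pd.Series, Mapping[str, float], None]) -> np.ndarray:
        if not self._frozen_tfs:
            return np.zeros(0)
        if x is None or not isinstance(x, (pd.Series, Mapping)):
            return np.zeros(len(self._frozen_tfs))
        get = (lambda g: float(x.get(g, 0.0))) if isinstance(x, pd.Series) else (
            lambda g: float(x.get(g, 0.0))
        )
        return np.array([get(g) for g in self._frozen_gene_ids])

    def _as_kd(self, kd) -> KdVector:
        if isinstance(kd, KdVector):
            if list(kd.tfs) != self.tfs:
                raise ValueError("KdVector roster does not match model roster")
            return kd
        if isinstance(kd, pd.Series):
            return KdVector(
                self.tfs,
                kd.reindex(self.tfs).to_numpy(dtype=float),
                kd.reindex(self.tfs).to_numpy(dtype=float),
                np.zeros(len(self.tfs), dtype=bool),
            )
        return KdVector.uniform(self.tfs, float(kd))

    # -- vectorized forward model -------------------------------------------

    def _class_flux(self, cls: _PairClass, Xa: np.ndarray, KD: np.ndarray, KI: np.ndarray):
        """Signed per-gene flux (B, G) of one region class; also returns per-pair r."""
        B = Xa.shape[0]
        if cls.n_pairs == 0:
            return np.zeros((B, len(self.genes))), np.zeros((B, 0))
        A = Xa[:, cls.tf_col]  # (B,P)
        kd = KD[:, cls.pair_tf]  # (B,P)
        R = Xa[:, cls.rep_col]  # (B,P,4)
        ki_r = KI[:, cls.rep_tf.ravel()].reshape(B, *cls.rep_tf.shape)
        repterm = cls.wq * (kd[..., None] / ki_r) * R
        wA = cls.w * A[..., None]
        r = (wA / (kd[..., None] + wA + repterm)).sum(axis=-1)
        if cls.se_idx.size:
            se = cls.se_idx
            active = cls.rank[se] <= cls.n_sites[se][:, None]
            wAp = cls.w[se] * np.where(active, A[:, se, None] ** cls.rank[se], 0.0)
            num = wAp.sum(axis=-1)
            den = kd[:, se] ** cls.n_sites[se] + num + repterm[:, se].sum(axis=-1)
            r[:, se] = np.where(den > 0, num / den, 0.0)
        safe = np.where(r > 0, r, 1.0)
        contrib = np.where(r > 0, self.params.kc * np.exp(-1.0 / safe), 0.0)
        return contrib @ cls.signed_M, r

    def _flux_terms(self, X: np.ndarray, KD: np.ndarray, KI: np.ndarray, frozen: np.ndarray):
        """Promoter and gene-body flux terms (each (B, G)) for batched states."""
        B = X.shape[0]
        Xa = np.concatenate(
            [X, np.tile(frozen, (B, 1)), np.zeros((B, 1))], axis=1
        )
        prom, _ = self._class_flux(self._promoter, Xa, KD, KI)
        body, _ = self._class_flux(self._body, Xa, KD, KI)
        return prom, body

    def _step_batch(self, X: np.ndarray, KD: np.ndarray, KI: np.ndarray, frozen: np.ndarray):
        prom, body = self._flux_terms(X, KD, KI, frozen)
        f = np.maximum(prom - body, 0.0)
        return f + degrade(X, self.params.d)

    # -- public simulation API ----------------------------------------------

    def step(self, state: pd.Series, kd=1.0) -> pd.Series:
        """One synchronous update x' = f(x) + g(x) of every roster gene."""
        kdv = self._as_kd(kd)
        x = self._as_state(state)
        frozen = self._frozen_from(state)
        X = self._step_batch(
            x[None, :], kdv.kd[None, :], kdv.ki[None, :], frozen
        )[0]
        return pd.Series(X, index=self.genes)

    def simulate(
        self,
        x0: pd.Series,
        n_steps: int,
        kd=1.0,
        return_trajectory: bool = False,
    ):
        """Iterate the update map ``n_steps`` times from ``x0``.

        Returns the final state as a Series, or the full (n_steps+1, G)
        trajectory DataFrame when ``return_trajectory`` is set.
        """
        kdv = self._as_kd(kd)
        x = self._as_state(x0)
        frozen = self._frozen_from(x0)
        KD, KI = kdv.kd[None, :], kdv.ki[None, :]
        traj = [x.copy()]
        for _ in range(n_steps):
            x = self._step_batch(x[None, :], KD, KI, frozen)[0]
            if return_trajectory:
                traj.append(x.copy())
        if return_trajectory:
            return pd.DataFrame(traj, columns=self.genes)
        return pd.Series(x, index=self.genes)

    def simulate_batch(
        self, x0: np.ndarray, n_steps: int, KD: np.ndarray, KI: np.ndarray, frozen: np.ndarray
    ) -> np.ndarray:
        """Batched simulation used by the fitter: x0 (B,G), KD/KI (B,T)."""
        X = x0
        for _ in range(n_steps):
            X = self._step_batch(X, KD, KI, frozen)
        return X

    # -- fitting / analysis entry points -------------------------------------

    def fit(self, x_init, x_ref, config=None, fixed=None):
        """Fit per-TF Kd by gradient descent; returns a :class:`TRNFitResult`."""
        from .fitting import FitConfig, fit_kd

        return fit_kd(self, x_init, x_ref, config or FitConfig(), fixed=fixed)

    def derivative_factors(self, state: pd.Series, kd=1.0):
        from .fitting import derivative_factors

        return derivative_factors(self, state, self._as_kd(kd))
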