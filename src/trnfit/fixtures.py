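"""Self-contained synthetic inputs with a known ground-truth network.

The generator emits a toy genome (one chromosome, one block per gene), GTF
gene models on both strands, per-assay peak files whose merged unions
reproduce the intended promoter and gene-body open regions, high-information
JASPAR motifs (one dominant base per position, so planted consensus sites
score exactly 1), and initial / reference expression tables.

The initial expression table plays the role of measured RNA-seq input: a
log-normal draw with median 1 (expression in units of the degradation
Michaelis constant).  The reference expression is produced by the forward
model itself: the ground-truth model is simulated from the initial state
over the fit horizon (optionally under perturbed Kd values), then
multiplied by log-normal noise emulating RNA-seq measurement error.  The
reference is therefore always exactly reachable by the model class, and
Kd perturbations planted here are recoverable in principle.  An optional
burn-in relaxes the initial draw under the ground-truth model first.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import ModelParams, TRNModel
from .motifs import ScoreMatrix, normalize_pfm
from .regions import GeneModel, GenomicInterval, call_open_regions, classify_regions
from . import io, motifs as motif_mod

_BASES = np.array(list("ACGT"))
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and ground-truth parameters of a generated fixture.

    Defaults give a desk-scale network: 30 TFs regulating 60 genes with
    1 kb open promoters.  true_kd is the generative dissociation constant
    shared by every TF (scalar) or given per TF; perturbed_tfs maps tf_id
    to a fold change applied to its true Kd when producing the reference
    expression.  noise_sigma is the log-normal measurement noise on the
    reference table.
    """

    n_tfs: int = 30
    n_genes: int = 60
    promoter_length: int = 1000
    motif_width: int = 16
    gene_body_length: int = 800
    true_kd: float = 1.0
    perturbed_tfs: Mapping[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.05
    seed: int = 0
    burn_in: int = 0
    ref_horizon: int = 5
    max_regulators: int = 2
    n_peripheral: int = 2
    peripheral_expression: float = 0.02
    se_fraction: float = 0.1
    body_region_fraction: float = 0.5
    body_site_fraction: float = 0.6
    repressor_only_fraction: float = 0.1
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must be <= n_genes")
        if self.motif_width > self.promoter_length:
            raise ValueError("motif longer than promoter")


@dataclass
class FixtureBundle:
    """In-memory fixture plus everything needed to write it to disk."""

    config: FixtureConfig
    genome: dict  # chrom -> str
    genes: list  # GeneModel
    peaks: list  # GenomicInterval
    matrices: list  # ScoreMatrix
    pfm_counts: dict  # tf_id -> (4, w) counts
    tf_table: pd.DataFrame
    annotations: list
    promoter_profiles: pd.DataFrame
    gene_body_profiles: pd.DataFrame
    model: TRNModel
    x_init: pd.Series
    x_ref: pd.Series
    true_kd: pd.Series
    planted_sites: pd.DataFrame
    perturbed: pd.DataFrame
    peripheral_tfs: list = field(default_factory=list)

    def tf_concentrations(self, expression: pd.Series) -> dict:
        gene_of = self.tf_table["gene_id"]
        return {t: float(expression.get(gene_of[t], 0.0)) for t in self.tf_table.index}

    def write(self, out_dir: str) -> None:
        """Write the standard-format files plus ground_truth/*.csv."""
        os.makedirs(out_dir, exist_ok=True)
        gt = os.path.join(out_dir, "ground_truth")
        os.makedirs(gt, exist_ok=True)
        with open(os.path.join(out_dir, "genome.fa"), "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(os.path.join(out_dir, "genes.gtf"), "w") as fh:
            for g in self.genes:
                lo, hi = g.span
                fh.write(
                    f"{g.chrom}\ttrnfit\tgene\t{lo + 1}\t{hi + 1}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}";\n'
                )
        by_assay: dict[str, list[GenomicInterval]] = {}
        for p in self.peaks:
            by_assay.setdefault(p.assay, []).append(p)
        for assay, plist in sorted(by_assay.items()):
            with open(os.path.join(out_dir, f"{assay}.bed"), "w") as fh:
                for p in sorted(plist, key=lambda q: (q.chrom, q.start)):
                    fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
        with open(os.path.join(out_dir, "motifs.pfm"), "w") as fh:
            for m in self.matrices:
                counts = self.pfm_counts[m.tf_id]
                fh.write(f">{m.tf_id} {m.tf_id}\n")
                for bi, base in enumerate("ACGT"):
                    row = " ".join(f"{int(c):3d}" for c in counts[bi])
                    fh.write(f"{base} [ {row} ]\n")
        io.write_expression(self.x_init, os.path.join(out_dir, "expression_initial.tsv"))
        io.write_expression(self.x_ref, os.path.join(out_dir, "expression_reference.tsv"))
        self.tf_table.to_csv(os.path.join(out_dir, "tf_table.tsv"), sep="\t", index=False)
        self.planted_sites.to_csv(os.path.join(gt, "planted_sites.csv"), index=False)
        pd.DataFrame({"tf_id": self.true_kd.index, "true_kd": self.true_kd.values}).to_csv(
            os.path.join(gt, "true_kd.csv"), index=False
        )
        self.perturbed.to_csv(os.path.join(gt, "perturbed_tfs.csv"), index=False)
        pd.DataFrame({"tf_id": self.peripheral_tfs}).to_csv(
            os.path.join(gt, "peripheral_tfs.csv"), index=False
        )


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _revcomp(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


def _plant(
    seq: np.ndarray,
    occupied: list,
    rng: np.random.Generator,
    lo: int,
    hi: int,
    site: str,
) -> Optional[int]:
    """Place a motif occurrence at a random non-overlapping offset; None if crowded."""
    w = len(site)
    idx = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in site])
    for _ in range(200):
        off = int(rng.integers(lo, hi - w))
        if all(off + w <= s or off >= e for s, e in occupied):
            seq[off : off + w] = idx
            occupied.append((off, off + w))
            return off
    return None


def generate(config: Optional[FixtureConfig] = None) -> FixtureBundle:
    """Build a complete fixture with recorded ground truth.

    Deterministic: the same config (including seed) yields byte-identical
    outputs.  The region caller and motif scanner of this package are used
    to derive the annotations and binding profiles, so the fixture always
    passes those stages with zero skipped genes.
    """
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    PL, W, BW = cfg.promoter_length, cfg.motif_width, cfg.gene_body_length
    block = PL + BW + 1000
    chrom = "chr1"
    tf_ids = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]
    gene_ids = [f"G{i + 1:03d}" for i in range(cfg.n_genes)]

    # motifs: one dominant base per position -> planted consensus scores 1
    matrices: list[ScoreMatrix] = []
    pfm_counts: dict[str, np.ndarray] = {}
    for t in tf_ids:
        dom = _random_sequence(rng, W)
        counts = np.ones((4, W))
        counts[dom, np.arange(W)] = 17
        pfm_counts[t] = counts
        matrices.append(normalize_pfm(counts, tf_id=t))
    consensus = {m.tf_id: m.consensus() for m in matrices}

    genome = np.zeros(cfg.n_genes * block + 500, dtype=np.int64)
    genome[:] = _random_sequence(rng, genome.size)
    genes: list[GeneModel] = []
    peaks: list[GenomicInterval] = []
    prom_bounds: dict[str, tuple[int, int]] = {}
    body_bounds: dict[str, tuple[int, int]] = {}
    for i, gid in enumerate(gene_ids):
        base = i * block
        minus = i % 2 == 1
        if not minus:
            p0 = base + 200
            p1 = p0 + PL
            tss = p0 + PL // 2
            tes = tss + BW
            body = (p1 + 50, min(p1 + 350, tes))
        else:
            tes = base + 200
            tss = tes + BW
            p0 = tss - PL // 2
            p1 = p0 + PL
            body = (max(tes, p0 - 350), p0 - 50)
        genes.append(GeneModel(gid, chrom, "-" if minus else "+", tss, tes))
        prom_bounds[gid] = (p0, p1)
        # promoter: histone + atac peaks whose union is exactly [p0, p1)
        peaks.append(GenomicInterval(chrom, p0, p0 + int(PL * 0.6), "histone_chip"))
        peaks.append(GenomicInterval(chrom, p0 + int(PL * 0.4), p1, "atac"))
        if body[0] < body[1] and rng.random() < cfg.body_region_fraction:
            mid = (body[0] + body[1]) // 2
            peaks.append(GenomicInterval(chrom, body[0], mid + 20, "histone_chip"))
            peaks.append(GenomicInterval(chrom, mid - 20, body[1], "dnase"))
            body_bounds[gid] = body
        # decoy histone-only peak in the intergenic margin: must be excluded
        peaks.append(GenomicInterval(chrom, base + block - 300, base + block - 200, "histone_chip"))

    # a few TFs stay peripheral: motif and expression present but no
    # planted sites, mirroring TFs with no open-chromatin targets in a
    # given cell state; the remaining regulator slots are dealt from a
    # balanced pool so every connected TF has a comparable out-degree and
    # is identifiable in principle
    peripheral = [str(t) for t in rng.choice(tf_ids, size=cfg.n_peripheral, replace=False)]
    connected = [t for t in tf_ids if t not in peripheral]
    peripheral_genes = {gene_ids[tf_ids.index(t)] for t in peripheral}
    se_gene = rng.random(cfg.n_genes) < cfg.se_fraction
    n_reg_per_gene = np.where(
        se_gene, 1, rng.integers(1, cfg.max_regulators + 1, size=cfg.n_genes)
    )
    # peripheral TFs are neither regulators nor induced: their own genes
    # get no planted regulators, so their expression decays over the horizon
    for i, gid in enumerate(gene_ids):
        if gid in peripheral_genes:
            n_reg_per_gene[i] = 0
            se_gene[i] = False
    total_slots = int(n_reg_per_gene.sum())
    base, extra = divmod(total_slots, len(connected))
    counts = np.full(len(connected), base)
    counts[rng.choice(len(connected), size=extra, replace=False)] += 1
    pool = list(rng.permutation(np.repeat(np.array(connected, dtype=object), counts)))

    plant_rows = []
    for i, gid in enumerate(gene_ids):
        p0, p1 = prom_bounds[gid]
        occupied: list[tuple[int, int]] = []
        local = np.zeros(p1 - p0, dtype=np.int64)  # offsets relative to p0
        local[:] = genome[p0:p1]
        regs: list[str] = []
        for _ in range(int(n_reg_per_gene[i])):
            k = next((j for j, t in enumerate(pool) if t not in regs), None)
            if k is None:
                break
            regs.append(str(pool.pop(k)))
        if se_gene[i]:
            chosen = {regs[0]: 4} if regs else {}
        else:
            chosen = {t: int(rng.integers(2, 4)) for t in regs}
        for t in sorted(chosen):
            for _ in range(chosen[t]):
                strand = "-" if rng.random() < 0.3 else "+"
                site = consensus[t] if strand == "+" else _revcomp(consensus[t])
                off = _plant(local, occupied, rng, 10, p1 - p0 - 10, site)
                if off is not None:
                    plant_rows.append((gid, t, "promoter", p0 + off, strand, 1.0))
        genome[p0:p1] = local
        if gid in body_bounds and rng.random() < cfg.body_site_fraction:
            b0, b1 = body_bounds[gid]
            t = str(rng.choice(connected))
            blocal = np.zeros(b1 - b0, dtype=np.int64)
            blocal[:] = genome[b0:b1]
            bocc: list[tuple[int, int]] = []
            off = _plant(blocal, bocc, rng, 2, b1 - b0 - 2, consensus[t])
            if off is not None:
                plant_rows.append((gid, t, "gene_body", b0 + off, "+", 1.0))
                genome[b0:b1] = blocal

    genome_str = "".join(_BASES[genome])
    genome_map = {chrom: genome_str}
    planted = pd.DataFrame(
        plant_rows, columns=["gene_id", "tf_id", "region_class", "offset", "strand", "sp"]
    )

    n_rep_only = int(round(cfg.repressor_only_fraction * cfg.n_tfs))
    rep_only = set(rng.choice(tf_ids, size=n_rep_only, replace=False)) if n_rep_only else set()
    tf_table = pd.DataFrame(
        {
            "tf_id": tf_ids,
            "gene_id": gene_ids[: cfg.n_tfs],
            "is_repressor_only": [t in rep_only for t in tf_ids],
        }
    ).set_index("tf_id", drop=False)

    annotations = classify_regions(call_open_regions(peaks), genes)

    true_kd = pd.Series(float(cfg.true_kd), index=tf_ids, name="true_kd")

    x_init = pd.Series(
        rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n_genes), index=gene_ids
    )
    # peripheral TFs are inactive in this cell state: unconnected and lowly
    # expressed, so they neither activate nor get selected as competitors
    for t in peripheral:
        x_init[tf_table.loc[t, "gene_id"]] *= cfg.peripheral_expression
    if cfg.burn_in > 0:
        # optional relaxation: bootstrap profiles with the raw draw, relax,
        # then rebuild so repressor selection saw the written initial state
        conc0 = {t: float(x_init[tf_table.loc[t, "gene_id"]]) for t in tf_ids}
        prom0, body0 = motif_mod.build_profiles(
            annotations, genome_map, matrices, conc0, a=cfg.params.a
        )
        model0 = TRNModel(prom0, body0, tf_table, cfg.params)
        x_init = model0.simulate(x_init, cfg.burn_in, kd=true_kd)
    conc = {t: float(x_init[tf_table.loc[t, "gene_id"]]) for t in tf_ids}
    prom_df, body_df = motif_mod.build_profiles(
        annotations, genome_map, matrices, conc, a=cfg.params.a
    )
    model = TRNModel(prom_df, body_df, tf_table, cfg.params)

    kd_ref = true_kd.copy()
    for t, fold in cfg.perturbed_tfs.items():
        if t not in kd_ref.index:
            raise ValueError(f"unknown tf_id in perturbed_tfs: {t}")
        kd_ref[t] *= float(fold)
    x_ref_clean = model.simulate(x_init, cfg.ref_horizon, kd=kd_ref)
    noise_rng = np.random.default_rng([cfg.seed, 7])
    noise = np.exp(noise_rng.normal(0.0, cfg.noise_sigma, size=cfg.n_genes))
    x_ref = pd.Series(x_ref_clean.values * noise, index=gene_ids)

    perturbed = pd.DataFrame(
        {
            "tf_id": list(cfg.perturbed_tfs),
            "fold_change": [cfg.perturbed_tfs[t] for t in cfg.perturbed_tfs],
        }
    )
    return FixtureBundle(
        config=cfg,
        genome=genome_map,
        genes=genes,
        peaks=peaks,
        matrices=matrices,
        pfm_counts=pfm_counts,
        tf_table=tf_table,
        annotations=annotations,
        promoter_profiles=prom_df,
        gene_body_profiles=body_df,
        model=model,
        x_init=x_init,
        x_ref=x_ref,
        true_kd=true_kd,
        planted_sites=planted,
        perturbed=perturbed,
        peripheral_tfs=peripheral,
    )


def default_perturbation_targets(bundle: FixtureBundle, n: int = 3) -> list[str]:
    """The n most-expressed TFs: the standard targets for Kd perturbations.

    A TF whose nuclear concentration is near zero binds essentially nothing
    whatever its Kd, so perturbing it leaves no trace in the expression
    data and its Kd is unidentifiable in principle; likewise a peripheral
    TF with no planted sites.  Perturbation experiments therefore target
    well-expressed, connected regulators.
    """
    with_sites = set(bundle.planted_sites["gene_id"].groupby(bundle.planted_sites["tf_id"]).count().index)
    conc = pd.Series(bundle.tf_concentrations(bundle.x_init))
    conc = conc[conc.index.isin(with_sites)]
    return list(conc.sort_values(ascending=False).index[:n])


def perturb_reference(
    bundle: FixtureBundle, tf_fold_changes: Mapping[str, float], seed: int
) -> pd.Series:
    """Regenerate the reference expression under modified ground-truth Kd.

    Forward-simulates the bundle's model from its initial state over the
    configured reference horizon with the given Kd fold changes, applies
    fresh seeded measurement noise, and updates the bundle's ground-truth
    perturbation table.  The noise seed changes the noise only, never the
    underlying clean trajectory or the ground truth.
    """
    kd = bundle.true_kd.copy()
    for t, fold in tf_fold_changes.items():
        if t not in kd.index:
            raise ValueError(f"unknown tf_id: {t}")
        kd[t] *= float(fold)
    clean = bundle.model.simulate(bundle.x_init, bundle.config.ref_horizon, kd=kd)
    noise_rng = np.random.default_rng([seed, 7])
    noise = np.exp(noise_rng.normal(0.0, bundle.config.noise_sigma, size=len(clean)))
    x_ref = pd.Series(clean.values * noise, index=clean.index)
    bundle.perturbed = pd.DataFrame(
        {
            "tf_id": list(tf_fold_changes),
            "fold_change": [tf_fold_changes[t] for t in tf_fold_changes],
        }
    )
    bundle.x_ref = x_ref
    return x_ref


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
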