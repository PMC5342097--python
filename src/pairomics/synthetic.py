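"""Synthetic paired tumor/control multi-omics cohorts with known truth.

The generator emulates a matched-pairs lung-tissue study: each patient
contributes one tumor and one control sample, measured on three layers
(miRNA, mRNA, protein). Abundances are log-normal. On the natural-log
scale a value is

    mu_f + beta_{f,p} + delta_f * 1[tumor] + eps

with a per-feature baseline mu_f, a per-feature-per-patient effect
beta_{f,p} shared by the patient's two samples (the inter-individual
variation that the paired design removes), an intrinsic tumor shift
delta_f for the deregulated fraction, and i.i.d. measurement noise eps.

miRNA-driven repression is injected through the stoichiometric influence
model itself: edge weights and per-condition joint influence scores are
computed from the noise-free condition means, and each targeted gene's
tumor abundance is multiplied by exp(-kappa * rel_delta) where rel_delta is
the relative change in joint influence. Proteins follow their coding gene's
per-sample abundance plus a protein-specific offset and extra noise.
Genomic coordinates tile the (real-sized) chromosomes; an opt-in hotspot
mode instead places every deregulated feature inside a shared 1-Mb region
so window-scan recovery can be verified exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    FeatureAnnotation,
    InteractionTable,
    OmicsKind,
    ProteinGeneMap,
    SampleDesign,
)
from .influence import compute_edge_weights, joint_influence_scores

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "GRCH38_CHROM_LENGTHS",
    "generate_interaction_network",
    "generate_cohort",
]

#: Approximate GRCh38 chromosome lengths (bp), canonical order, ~3.1 Gb total.
GRCH38_CHROM_LENGTHS: dict[str, int] = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468, "X": 156_040_895, "Y": 57_227_415,
}

#: Floor protecting the relative influence change against near-zero baselines.
INFLUENCE_FLOOR = 1e-6


def mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(1, n + 1)]


def gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def protein_ids(n: int) -> list[str]:
    return [f"PROT{i:04d}" for i in range(1, n + 1)]


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults emulate a scaled-down study.

    The cohort size (18 matched pairs) matches the study design the
    generator emulates; the feature counts are a tractable scale-down of
    2,549 miRNAs / 34,687 genes / 6,183 proteins keeping their ordering.
    Effect sizes are log2 shifts; all noise standard deviations are on the
    natural-log abundance scale.
    """

    n_patients: int = 18
    n_mirna: int = 100
    n_gene: int = 800
    n_protein: int = 300
    mean_targets_per_mirna: float = 8.0
    fraction_functional: float = 0.3
    fraction_deregulated_mirna: float = 0.3
    fraction_deregulated_gene: float = 0.05
    fraction_deregulated_protein: float = 0.05
    effect_size_log2: float = 1.5
    coupling_strength: float = 1.0  # kappa
    protein_noise_sd: float = 0.5
    feature_noise_sd: float = 0.3
    patient_baseline_sd: float = 0.5
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    hotspot: bool = False
    hotspot_chromosome: str = "5"
    hotspot_start: int = 10_000_001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_patients", "n_mirna", "n_gene", "n_protein"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_protein > self.n_gene:
            raise ValueError("n_protein cannot exceed n_gene (1:1 coding map)")
        for name in (
            "protein_noise_sd", "feature_noise_sd", "patient_baseline_sd",
            "baseline_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "fraction_functional", "fraction_deregulated_mirna",
            "fraction_deregulated_gene", "fraction_deregulated_protein",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")


@dataclass
class GroundTruth:
    """Injected deregulation per feature, recorded at generation time.

    ``true_direction`` is up/down/none per feature; for targeted genes
    ``delta_influence_sign`` records the sign of the noise-free change in
    joint influence (+1, -1 or 0).
    """

    table: pd.DataFrame  # feature_id, omics_kind, true_direction, delta_influence_sign

    def __post_init__(self) -> None:
        if self.table["feature_id"].duplicated().any():
            raise ValueError("every feature must appear exactly once in the truth")

    def directions(self, kind: OmicsKind | str | None = None) -> pd.Series:
        t = self.table
        if kind is not None:
            t = t[t["omics_kind"] == OmicsKind(kind).value]
        return t.set_index("feature_id")["true_direction"]


@dataclass
class SyntheticCohort:
    """Everything one simulated study produces."""

    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    protein: ExpressionMatrix
    design: SampleDesign
    annotation: FeatureAnnotation
    truth: GroundTruth
    network: InteractionTable
    protein_gene_map: ProteinGeneMap
    chrom_lengths: dict = field(default_factory=lambda: dict(GRCH38_CHROM_LENGTHS))


def generate_interaction_network(
    n_mirna: int,
    n_gene: int,
    mean_targets_per_mirna: float,
    seed: int,
    fraction_functional: float = 0.3,
) -> InteractionTable:
    """Random bipartite miRNA -> gene target network.

    Each miRNA's target count is 1 + Poisson(mean - 1), so counts are >= 1
    with the requested mean; targets are drawn without replacement and a
    ``fraction_functional`` of edges is flagged as functionally validated.
    """
    if n_mirna < 1 or n_gene < 1:
        raise ValueError("counts must be >= 1")
    if mean_targets_per_mirna < 1:
        raise ValueError("mean_targets_per_mirna must be >= 1")
    if mean_targets_per_mirna > n_gene:
        raise ValueError("mean_targets_per_mirna cannot exceed n_gene")
    rng = np.random.default_rng(seed)
    mirnas = mirna_ids(n_mirna)
    genes = np.array(gene_ids(n_gene))
    records = []
    for mirna in mirnas:
        k = min(1 + rng.poisson(mean_targets_per_mirna - 1), n_gene)
        targets = rng.choice(genes, size=k, replace=False)
        for gene in targets:
            support = (
                "functional_strong"
                if rng.random() < fraction_functional
                else "other"
            )
            records.append((mirna, gene, support))
    table = pd.DataFrame(records, columns=["mirna_id", "gene_id", "support"])
    return InteractionTable(table.sort_values(["mirna_id", "gene_id"]).reset_index(drop=True))


def _pick_directions(rng, ids, fraction) -> pd.Series:
    """Choose a deregulated subset and assign up/down 50/50."""
    out = pd.Series("none", index=pd.Index(ids), dtype=object)
    n_dereg = int(round(fraction * len(ids)))
    if n_dereg:
        chosen = rng.choice(len(ids), size=n_dereg, replace=False)
        signs = rng.random(n_dereg) < 0.5
        out.iloc[chosen] = np.where(signs, "up", "down")
    return out


def _layer_logs(rng, mu, beta, delta_log, n_patients, noise_sd):
    """Tumor and control natural-log abundance grids (features x patients)."""
    eps_t = rng.normal(0, noise_sd, size=beta.shape)
    eps_c = rng.normal(0, noise_sd, size=beta.shape)
    log_t = mu[:, None] + beta + delta_log[:, None] + eps_t
    log_c = mu[:, None] + beta + eps_c
    return log_t, log_c


def generate_cohort(
    config: SimulationConfig, network: InteractionTable | None = None
) -> SyntheticCohort:
    """Simulate one paired cohort with known ground truth.

    If no interaction network is given, one is generated from the config.
    The returned cohort bundles the three expression matrices, the sample
    design, genomic annotation, interaction network, protein-gene map and
    the injected truth.
    """
    rng = np.random.default_rng(config.seed)
    if network is None:
        network = generate_interaction_network(
            config.n_mirna,
            config.n_gene,
            config.mean_targets_per_mirna,
            seed=int(rng.integers(2**31)),
            fraction_functional=config.fraction_functional,
        )
    mirnas = mirna_ids(config.n_mirna)
    genes = gene_ids(config.n_gene)
    proteins = protein_ids(config.n_protein)
    if not set(network.mirnas) <= set(mirnas) or not set(network.genes) <= set(genes):
        raise ValueError("network features are not a subset of configured features")

    n_p = config.n_patients
    patients = [f"P{i:02d}" for i in range(1, n_p + 1)]
    ln2 = np.log(2.0)
    effect = config.effect_size_log2 * ln2

    # --- miRNA layer ------------------------------------------------------
    mu_m = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_mirna)
    dir_m = _pick_directions(rng, mirnas, config.fraction_deregulated_mirna)
    delta_m = np.where(dir_m == "up", effect, np.where(dir_m == "down", -effect, 0.0))
    beta_m = rng.normal(0, config.patient_baseline_sd, size=(config.n_mirna, n_p))
    log_m_t, log_m_c = _layer_logs(
        rng, mu_m, beta_m, delta_m, n_p, config.feature_noise_sd
    )

    # --- gene layer: intrinsic effects on untargeted genes only -----------
    mu_g = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_gene)
    targeted = set(network.genes)
    untargeted = [g for g in genes if g not in targeted]
    dir_g = pd.Series("none", index=pd.Index(genes), dtype=object)
    dir_g.loc[untargeted] = _pick_directions(
        rng, untargeted, config.fraction_deregulated_gene
    )
    delta_g = np.where(dir_g == "up", effect, np.where(dir_g == "down", -effect, 0.0))

    # noise-free condition means drive the coupling through the model itself
    true_gene_control_mean = pd.Series(np.exp(mu_g), index=genes)
    true_mirna_control = pd.Series(np.exp(mu_m), index=mirnas)
    true_mirna_tumor = pd.Series(np.exp(mu_m + delta_m), index=mirnas)
    weights = compute_edge_weights(network, true_gene_control_mean)
    scores = joint_influence_scores(weights, true_mirna_control, true_mirna_tumor)
    rel_delta = pd.Series(0.0, index=pd.Index(genes))
    rel = scores["delta"] / np.maximum(scores["s_control"], INFLUENCE_FLOOR)
    rel_delta.loc[scores.index] = rel
    kappa = config.coupling_strength
    coupling_shift = -kappa * rel_delta.to_numpy()

    beta_g = rng.normal(0, config.patient_baseline_sd, size=(config.n_gene, n_p))
    log_g_t, log_g_c = _layer_logs(
        rng, mu_g, beta_g, delta_g + coupling_shift, n_p, config.feature_noise_sd
    )
    # coupling-driven truth: repression when influence rises
    coupled = (rel_delta != 0) & (kappa > 0)
    dir_g[coupled & (rel_delta > 0)] = "down"
    dir_g[coupled & (rel_delta < 0)] = "up"

    # --- protein layer: follows the coding gene plus offset and noise -----
    gene_index = {g: i for i, g in enumerate(genes)}
    coding = [gene_index[g] for g in gene_ids(config.n_protein)]
    dir_p = _pick_directions(rng, proteins, config.fraction_deregulated_protein)
    delta_p = np.where(dir_p == "up", effect, np.where(dir_p == "down", -effect, 0.0))
    offset_p = rng.normal(0, 1.0, config.n_protein)
    noise_t = rng.normal(0, config.protein_noise_sd, size=(config.n_protein, n_p))
    noise_c = rng.normal(0, config.protein_noise_sd, size=(config.n_protein, n_p))
    log_p_t = log_g_t[coding] + offset_p[:, None] + delta_p[:, None] + noise_t
    log_p_c = log_g_c[coding] + offset_p[:, None] + noise_c

    # --- assemble matrices and design -------------------------------------
    tumor_ids = [f"{p}_T" for p in patients]
    control_ids = [f"{p}_C" for p in patients]

    def matrix(ids, log_t, log_c, kind):
        df = pd.DataFrame(
            np.hstack([np.exp(log_t), np.exp(log_c)]),
            index=ids,
            columns=tumor_ids + control_ids,
        )
        return ExpressionMatrix(df, kind)

    mirna_mat = matrix(mirnas, log_m_t, log_m_c, OmicsKind.MIRNA)
    mrna_mat = matrix(genes, log_g_t, log_g_c, OmicsKind.MRNA)
    protein_mat = matrix(proteins, log_p_t, log_p_c, OmicsKind.PROTEIN)

    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": tumor_ids + control_ids,
                "patient_id": patients + patients,
                "condition": ["tumor"] * n_p + ["control"] * n_p,
            }
        )
    )

    truth = GroundTruth(
        pd.DataFrame(
            {
                "feature_id": mirnas + genes + proteins,
                "omics_kind": [OmicsKind.MIRNA.value] * config.n_mirna
                + [OmicsKind.MRNA.value] * config.n_gene
                + [OmicsKind.PROTEIN.value] * config.n_protein,
                "true_direction": list(dir_m) + list(dir_g) + list(dir_p),
                "delta_influence_sign": [0] * config.n_mirna
                + list(np.sign(rel_delta.to_numpy()).astype(int))
                + [0] * config.n_protein,
            }
        )
    )

    annotation = _make_annotation(config, truth)
    mapping = ProteinGeneMap(
        pd.DataFrame({"protein_id": proteins, "gene_id": gene_ids(config.n_protein)})
    )
    return SyntheticCohort(
        mirna_mat, mrna_mat, protein_mat, design, annotation, truth, network, mapping
    )


def _make_annotation(config: SimulationConfig, truth: GroundTruth) -> FeatureAnnotation:
    """Tile features across the genome; optionally pile the deregulated ones
    into a shared sub-window of a 1-Mb hotspot."""
    lengths = GRCH38_CHROM_LENGTHS
    chroms = list(lengths)
    bounds = np.cumsum([0] + [lengths[c] for c in chroms])
    total = int(bounds[-1])
    records = []
    widths = {
        OmicsKind.MIRNA.value: 80,
        OmicsKind.MRNA.value: 20_000,
        OmicsKind.PROTEIN.value: 20_000,
    }
    t = truth.table
    for kind in widths:
        feats = t[t["omics_kind"] == kind]["feature_id"].tolist()
        spacing = total // (len(feats) + 1)
        width = widths[kind]
        for i, fid in enumerate(feats):
            gpos = (i + 1) * spacing
            ci = int(np.searchsorted(bounds, gpos, side="right")) - 1
            chrom = chroms[ci]
            start = int(gpos - bounds[ci])
            start = max(1, min(start, lengths[chrom] - width))
            records.append((fid, kind, chrom, start, start + width - 1))
    ann = pd.DataFrame(
        records, columns=["feature_id", "omics_kind", "chromosome", "start", "end"]
    )
    if config.hotspot:
        dereg = t[t["true_direction"] != "none"]["feature_id"]
        span = 500_000  # keep everything inside half a window width
        n = max(len(dereg), 1)
        step = max(span // (n + 1), 1)
        pos = {fid: config.hotspot_start + (i + 1) * step for i, fid in enumerate(dereg)}
        in_hot = ann["feature_id"].isin(pos)
        ann.loc[in_hot, "chromosome"] = config.hotspot_chromosome
        ann.loc[in_hot, "start"] = ann.loc[in_hot, "feature_id"].map(pos)
        ann.loc[in_hot, "end"] = ann.loc[in_hot, "start"] + 99
    return FeatureAnnotation(ann)
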