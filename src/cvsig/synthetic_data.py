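"""Synthetic perturbation-screen generator with planted ground truth.

The generator emulates the statistical structure that the analysis pipeline
assumes about large perturbation-transcriptomics / viability screen pairs
(LINCS-L1000-style signatures matched to CTRP-style compound viability and
Achilles-style shRNA depletion):

* a single unit-norm *viability loading vector* ``w`` shared by the compound
  and shRNA screens — the planted cell-viability signature (CVS).  Cell death
  moves a signature along ``-w`` in proportion to the viability burden;
* per-MoA signature components ``m_k`` (orthogonalized against ``w``), so
  compounds with a shared mechanism are similar beyond their toxicity;
* per-cell-line offset vectors, reused between perturbation signatures and
  baseline expression;
* logistic dose–response viability for compounds (fraction metric, one assay
  time point) and essentiality-driven log fold changes for shRNAs
  (log_fold_change metric) — deliberately *not* rescaled to each other;
* time maturation g(tau): early (3/6 h) compound signatures carry only a
  fraction of the viability component;
* baseline expression, doubling time, tissue/MSI annotations and a drug
  sensitivity (AUC) table with planted general-level-of-drug-sensitivity
  (GLDS) offsets correlated with the per-cell CVS propensity rho_c.

Every latent is reproducible from ``(WorldConfig, seed)``; randomness is
drawn from per-entity sub-streams so adding entities does not shuffle
existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AnnotationTable, SignatureSet, ViabilityTable

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "BaselinePanel",
    "build_world",
    "toxicity_spanning_config",
    "simulate_compound_screen",
    "simulate_shrna_screen",
    "simulate_baseline_panel",
    "simulate_fingerprints",
    "moa_annotation",
    "nci60_like_benchmark",
]

# stream codes for per-purpose RNG sub-streams
_S_LATENTS, _S_COMPOUND, _S_SHRNA, _S_BASELINE, _S_FINGERPRINT = range(5)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class WorldConfig:
    """All knobs of the synthetic world; the defaults are the study conditions.

    Counts and noise scales mirror a scaled-down screen pair: 300 landmark
    genes, 12 cell lines, 60 compounds in 10 MoA classes at 4 doses and
    3 time points, 150 shRNAs at 3 late time points.  ``maturation`` encodes
    the finding that the viability component of a compound signature is weak
    at 3/6 h and fully developed at 24 h; shRNA signatures (measured days
    after infection) are always mature.
    """

    seed: int
    n_genes: int = 300
    n_cells: int = 12
    n_moa_classes: int = 10
    n_compounds: int = 60
    n_shrnas: int = 150
    doses_um: tuple = (0.37, 1.1, 3.3, 10.0)
    compound_times_h: tuple = (3.0, 6.0, 24.0)
    shrna_times_h: tuple = (96.0, 120.0, 144.0)
    viability_sparsity: float = 0.3      # fraction of genes in the support of w
    sigma_x: float = 1.0                 # per-gene signature noise (z-score units)
    sigma_v: float = 0.05                # viability noise (fraction metric)
    sigma_lfc: float = 0.1               # shRNA log-fold-change noise
    maturation: tuple = ((3.0, 0.2), (6.0, 0.5), (24.0, 1.0))
    kappa: float = 3.0                   # viability amplitude of the w component
    kappa_shrna: float = 1.0             # LFC -> signature scale on w
    moa_scale: float = 1.0               # amplitude of the shared m_k component
    drug_scale: float = 1.5              # per-drug idiosyncratic (off-target) component
    cell_scale: float = 0.15             # per-gene SD of cell offsets
    dose_response_width: float = 0.3     # logistic width in log10 concentration
    toxic_class_log10_ic50: float = 0.0  # ~1 uM: reached within the dose range
    inert_class_log10_ic50: float = 2.5  # ~300 uM: never reached
    class_log10_ic50_sd: float = 0.25
    drug_log10_ic50_sd: float = 0.4
    cell_log10_ic50_sd: float = 0.2
    essential_fraction: float = 0.4
    essential_depth_mean: float = 2.0
    essential_depth_sd: float = 0.6
    essential_cell_sd: float = 0.3
    knockdown_depth: float = 2.0
    compound_assay_time_h: float = 72.0
    shrna_assay_time_h: float = 960.0
    n_tissues: int = 3
    baseline_mean: float = 8.0
    baseline_noise: float = 0.05
    doubling_time_h: float = 40.0
    doubling_rho_slope: float = 5.0
    doubling_tissue_sd: float = 3.0
    doubling_noise: float = 1.0
    auc_intercept: float = 0.7
    glds_scale: float = 0.1
    glds_rho_corr: float = 0.5
    sensitivity_potency_scale: float = -0.3  # toxic drugs -> lower AUC
    sensitivity_moa_scale: float = 0.08      # cell x MoA-class interaction
    sensitivity_noise: float = 0.05
    n_tfs: int = 15
    n_decoy_sets: int = 5
    fingerprint_bits: int = 256

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_moa_classes", "n_compounds",
                     "n_shrnas"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for _, g in self.maturation:
            if not 0 < g <= 1:
                raise ValueError("maturation factors must lie in (0, 1]")

    def maturation_of(self, time_h: float) -> float:
        for t, g in self.maturation:
            if t == time_h:
                return g
        return 1.0  # shRNA times and anything unlisted are fully mature


def toxicity_spanning_config(seed: int, **overrides) -> WorldConfig:
    """World where toxicity spans MoA classes instead of defining them.

    All compounds draw their potency from one wide distribution
    (log10 IC50 ~ N(0.9, 1.25) in log10 uM), so roughly half the drugs of
    *every* class are toxic within the tested dose range.  This is the
    regime in which cell death confounds mechanism-of-action similarity:
    toxicity carries no class information, yet toxic drug pairs look alike.
    The default config instead makes potency a class property (some classes
    toxic, some inert), which is the appropriate regime for the
    viability-prediction analyses.
    """
    params = dict(seed=seed, toxic_class_log10_ic50=0.9,
                  inert_class_log10_ic50=0.9, class_log10_ic50_sd=0.0,
                  drug_log10_ic50_sd=1.25)
    params.update(overrides)
    return WorldConfig(**params)


@dataclass
class SyntheticWorld:
    """All planted latents; the ground truth for every downstream test."""

    config: WorldConfig
    genes: pd.Index
    cells: pd.Index
    compounds: pd.Index
    shrnas: pd.Index
    w: pd.Series                      # unit-norm viability loading, sparse support
    moa_vectors: pd.DataFrame         # K x G, unit norm, orthogonal to w
    cell_offsets: pd.DataFrame        # C x G
    moa_of: pd.Series                 # compound -> class index
    drug_vectors: pd.DataFrame        # D x G idiosyncratic components
    log10_ic50: pd.DataFrame          # compounds x cells (log10 uM)
    essentiality: pd.DataFrame        # shRNAs x cells (>= 0 is essential depth)
    shrna_target: pd.Series           # shRNA -> gene_id
    rho: pd.Series                    # per-cell CVS propensity
    tissue: pd.Series
    msi: pd.Series
    glds: pd.Series                   # planted GLDS offsets (AUC units)
    cell_moa_affinity: pd.DataFrame   # C x K sensitivity interaction
    tf_alignment: pd.Series
    tf_regulons: dict = field(repr=False, default_factory=dict)
    tf_mean_essentiality: pd.Series = None
    gene_sets: dict = field(repr=False, default_factory=dict)

    @property
    def seed(self) -> int:
        return self.config.seed

    def moa_label(self, compound: str) -> str:
        return f"MOA{self.moa_of[compound]:02d}"


def build_world(config: WorldConfig) -> SyntheticWorld:
    """Draw every latent of the synthetic world from the seeded sub-streams."""
    cfg = config
    rng = _rng(cfg.seed, _S_LATENTS)

    genes = pd.Index([f"G{i:04d}" for i in range(cfg.n_genes)], name="gene_id")
    cells = pd.Index([f"CL{i:02d}" for i in range(cfg.n_cells)], name="cell_line_id")
    compounds = pd.Index([f"CPD{i:03d}" for i in range(cfg.n_compounds)],
                         name="perturbagen_id")
    shrnas = pd.Index([f"SH{i:03d}" for i in range(cfg.n_shrnas)],
                      name="perturbagen_id")

    # viability loading: standard normal on a sparse support, then unit norm
    n_support = max(2, int(round(cfg.viability_sparsity * cfg.n_genes)))
    support = rng.choice(cfg.n_genes, size=n_support, replace=False)
    w = np.zeros(cfg.n_genes)
    w[support] = rng.standard_normal(n_support)
    w /= np.linalg.norm(w)

    # MoA vectors: standard normal, orthogonalized against w, unit norm
    M = rng.standard_normal((cfg.n_moa_classes, cfg.n_genes))
    M -= np.outer(M @ w, w)
    M /= np.linalg.norm(M, axis=1, keepdims=True)

    cell_off = rng.standard_normal((cfg.n_cells, cfg.n_genes)) * cfg.cell_scale

    # per-drug idiosyncratic signature components (off-target profiles):
    # unit norm, so within-MoA-class consensus similarity is not saturated
    Dv = rng.standard_normal((cfg.n_compounds, cfg.n_genes))
    Dv /= np.linalg.norm(Dv, axis=1, keepdims=True)

    # compounds: round-robin MoA classes; the first half of the classes are
    # potent within the dose range, the rest inert
    moa_of = pd.Series(np.arange(cfg.n_compounds) % cfg.n_moa_classes,
                       index=compounds, name="moa_class")
    class_means = np.where(
        np.arange(cfg.n_moa_classes) < cfg.n_moa_classes // 2,
        cfg.toxic_class_log10_ic50, cfg.inert_class_log10_ic50,
    ) + rng.normal(0.0, cfg.class_log10_ic50_sd, cfg.n_moa_classes)
    drug_pot = class_means[moa_of.to_numpy()] + rng.normal(
        0.0, cfg.drug_log10_ic50_sd, cfg.n_compounds)
    log10_ic50 = pd.DataFrame(
        drug_pot[:, None] + rng.normal(0.0, cfg.cell_log10_ic50_sd,
                                       (cfg.n_compounds, cfg.n_cells)),
        index=compounds, columns=cells)

    # shRNAs: a fraction are essential with positive depletion depth
    is_ess = rng.random(cfg.n_shrnas) < cfg.essential_fraction
    base_e = np.where(
        is_ess,
        np.abs(rng.normal(cfg.essential_depth_mean, cfg.essential_depth_sd,
                          cfg.n_shrnas)),
        0.0)
    ess = pd.DataFrame(
        np.clip(base_e[:, None] + np.where(is_ess[:, None], 1.0, 0.0)
                * rng.normal(0.0, cfg.essential_cell_sd,
                             (cfg.n_shrnas, cfg.n_cells)), 0.0, None),
        index=shrnas, columns=cells)
    shrna_target = pd.Series(genes[rng.integers(0, cfg.n_genes, cfg.n_shrnas)],
                             index=shrnas, name="target_gene")

    # baseline latents
    rho = pd.Series(rng.standard_normal(cfg.n_cells), index=cells, name="rho")
    tissue = pd.Series([f"tissue{(i * cfg.n_tissues) // cfg.n_cells}"
                        for i in range(cfg.n_cells)], index=cells, name="tissue")
    msi = pd.Series(rng.random(cfg.n_cells) < 0.25, index=cells, name="msi")
    rho_z = (rho - rho.mean()) / rho.std(ddof=0)
    indep = rng.standard_normal(cfg.n_cells)
    indep = (indep - indep.mean()) / indep.std(ddof=0)
    r = cfg.glds_rho_corr
    glds = pd.Series(cfg.glds_scale * (r * rho_z + np.sqrt(1 - r * r) * indep),
                     index=cells, name="glds")
    affinity = pd.DataFrame(
        rng.standard_normal((cfg.n_cells, cfg.n_moa_classes)),
        index=cells, columns=range(cfg.n_moa_classes))

    # TF regulons: weight vectors partially aligned with w, plus decoy sets;
    # TFs aligned with the viability axis get proportional planted essentiality
    tf_names = [f"TF{i:02d}" for i in range(cfg.n_tfs)]
    tf_alignment = pd.Series(rng.standard_normal(cfg.n_tfs), index=tf_names)
    regulons = {}
    regulon_size = min(30, cfg.n_genes)
    for t, name in enumerate(tf_names):
        idx = rng.choice(cfg.n_genes, regulon_size, replace=False)
        weights = (tf_alignment.iloc[t] * 3.0 * w[idx]
                   + 0.2 * rng.standard_normal(regulon_size))
        regulons[name] = dict(zip(genes[idx], weights))
    tf_ess = pd.Series(
        tf_alignment.to_numpy() + 0.3 * rng.standard_normal(cfg.n_tfs),
        index=tf_names, name="mean_essentiality")

    gene_sets = {"viability_axis": {g: float(x) for g, x in zip(genes, w) if x != 0.0}}
    for d in range(cfg.n_decoy_sets):
        idx = rng.choice(cfg.n_genes, regulon_size, replace=False)
        gene_sets[f"decoy{d}"] = dict(
            zip(genes[idx], rng.standard_normal(regulon_size) * 0.3))

    return SyntheticWorld(
        config=cfg, genes=genes, cells=cells, compounds=compounds,
        shrnas=shrnas,
        w=pd.Series(w, index=genes, name="w"),
        moa_vectors=pd.DataFrame(M, index=range(cfg.n_moa_classes), columns=genes),
        cell_offsets=pd.DataFrame(cell_off, index=cells, columns=genes),
        moa_of=moa_of,
        drug_vectors=pd.DataFrame(Dv, index=compounds, columns=genes),
        log10_ic50=log10_ic50, essentiality=ess,
        shrna_target=shrna_target, rho=rho, tissue=tissue, msi=msi, glds=glds,
        cell_moa_affinity=affinity, tf_alignment=tf_alignment,
        tf_regulons=regulons, tf_mean_essentiality=tf_ess, gene_sets=gene_sets,
    )


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def _kill_fraction(world: SyntheticWorld, compound: str, dose_um) -> np.ndarray:
    """Logistic kill fraction per cell at the given dose (vector over cells)."""
    cfg = world.config
    z = (np.log10(dose_um) - world.log10_ic50.loc[compound].to_numpy())
    return _logistic(z / cfg.dose_response_width)


def simulate_compound_screen(world: SyntheticWorld):
    """CTRP-style compound screen: signatures at 3 times, viability at one.

    For compound p, cell c, dose d the kill fraction is
    ``f = logistic((log10 d - log10 IC50(p,c)) / width)``; the viability
    burden is ``u = kappa * f``; fraction viability is ``1 - f + noise``
    clipped at 0, recorded at a single assay time; and the signature at
    time tau is ``-g(tau) * u * w + b * m_k(p) + s * d_p + c_cell + noise``
    where ``d_p`` is the drug's idiosyncratic (off-target) component.
    """
    cfg = world.config
    G = cfg.n_genes
    n_cells, n_doses, n_times = cfg.n_cells, len(cfg.doses_um), len(cfg.compound_times_h)
    w = world.w.to_numpy()
    cell_off = world.cell_offsets.to_numpy()

    sig_rows, sig_ids, sig_meta = [], [], []
    viab_rows = []
    for pi, p in enumerate(world.compounds):
        rng = _rng(cfg.seed, _S_COMPOUND, pi)
        m = (cfg.moa_scale * world.moa_vectors.iloc[world.moa_of[p]].to_numpy()
             + cfg.drug_scale * world.drug_vectors.iloc[pi].to_numpy())
        eps = rng.normal(0.0, cfg.sigma_x, (n_cells, n_doses, n_times, G))
        v_eps = rng.normal(0.0, cfg.sigma_v, (n_cells, n_doses))
        for ci, c in enumerate(world.cells):
            for di, d in enumerate(cfg.doses_um):
                f = float(_kill_fraction(world, p, d)[ci])
                u = cfg.kappa * f
                viab_rows.append((c, p, d, max(0.0, 1.0 - f + v_eps[ci, di]),
                                  "fraction", cfg.compound_assay_time_h))
                for ti, tau in enumerate(cfg.compound_times_h):
                    g = cfg.maturation_of(tau)
                    x = -g * u * w + m + cell_off[ci] + eps[ci, di, ti]
                    sig_rows.append(x)
                    sig_ids.append(f"{p}:{c}:{d}:{tau:g}h")
                    sig_meta.append((c, p, "compound", d, tau))

    values = pd.DataFrame(np.asarray(sig_rows),
                          index=pd.Index(sig_ids, name="instance_id"),
                          columns=world.genes)
    row_meta = pd.DataFrame(
        sig_meta, index=values.index,
        columns=["cell_line_id", "perturbagen_id", "perturbagen_type",
                 "dose_um", "time_h"])
    viab = pd.DataFrame(
        viab_rows, columns=["cell_line_id", "perturbagen_id", "dose_um",
                            "viability", "metric_type", "assay_time_h"])
    return SignatureSet(values, row_meta, world_col_meta(world)), ViabilityTable(viab)


def simulate_shrna_screen(world: SyntheticWorld):
    """Achilles-style shRNA screen: depletion log fold changes, no dose.

    LFC(s, c) = -essentiality(s, c) + noise (log_fold_change metric).  The
    signature shares the planted w axis, ``g(tau) * LFC * kappa' * w``, plus
    a knockdown dip at the target gene, the cell offset and noise.
    """
    cfg = world.config
    G = cfg.n_genes
    n_cells, n_times = cfg.n_cells, len(cfg.shrna_times_h)
    w = world.w.to_numpy()
    cell_off = world.cell_offsets.to_numpy()
    gene_pos = pd.Series(np.arange(G), index=world.genes)

    sig_rows, sig_ids, sig_meta = [], [], []
    viab_rows = []
    for si, s in enumerate(world.shrnas):
        rng = _rng(cfg.seed, _S_SHRNA, si)
        eps = rng.normal(0.0, cfg.sigma_x, (n_cells, n_times, G))
        lfc_eps = rng.normal(0.0, cfg.sigma_lfc, n_cells)
        tpos = gene_pos[world.shrna_target[s]]
        for ci, c in enumerate(world.cells):
            lfc_clean = -float(world.essentiality.loc[s].iloc[ci])
            viab_rows.append((c, s, np.nan, lfc_clean + lfc_eps[ci],
                              "log_fold_change", cfg.shrna_assay_time_h))
            for ti, tau in enumerate(cfg.shrna_times_h):
                g = cfg.maturation_of(tau)
                x = (g * lfc_clean * cfg.kappa_shrna * w + cell_off[ci]
                     + eps[ci, ti])
                x = x.copy()
                x[tpos] -= cfg.knockdown_depth
                sig_rows.append(x)
                sig_ids.append(f"{s}:{c}:{tau:g}h")
                sig_meta.append((c, s, "shRNA", np.nan, tau))

    values = pd.DataFrame(np.asarray(sig_rows),
                          index=pd.Index(sig_ids, name="instance_id"),
                          columns=world.genes)
    row_meta = pd.DataFrame(
        sig_meta, index=values.index,
        columns=["cell_line_id", "perturbagen_id", "perturbagen_type",
                 "dose_um", "time_h"])
    viab = pd.DataFrame(
        viab_rows, columns=["cell_line_id", "perturbagen_id", "dose_um",
                            "viability", "metric_type", "assay_time_h"])
    return SignatureSet(values, row_meta, world_col_meta(world)), ViabilityTable(viab)


def world_col_meta(world: SyntheticWorld) -> pd.DataFrame:
    return pd.DataFrame({"gene_symbol": world.genes}, index=world.genes)


# ---------------------------------------------------------------------------
# baseline panel, fingerprints, external benchmark
# ---------------------------------------------------------------------------

@dataclass
class BaselinePanel:
    """GDSC/gCSI-style panel: baseline expression plus per-cell annotations
    and a (cell x drug) sensitivity table."""

    expression: pd.DataFrame      # genes x cells
    annotations: pd.DataFrame     # per cell: tissue, msi, doubling_time_h
    sensitivity: pd.DataFrame     # long: cell_line_id, drug_id, auc, ln_ic50


def drug_toxicity(world: SyntheticWorld) -> pd.Series:
    """Mean kill fraction per compound across cells at the top tested dose."""
    top = max(world.config.doses_um)
    return pd.Series({p: float(_kill_fraction(world, p, top).mean())
                      for p in world.compounds}, name="toxicity")


def simulate_baseline_panel(world: SyntheticWorld) -> BaselinePanel:
    """Baseline expression, doubling times and drug-sensitivity AUC table.

    baseline_c = mu0 + c_cell + rho_c * w (+ noise);
    doubling_time_c = T0 - lambda * rho_c + tissue effect + noise;
    AUC(c, p) = intercept + GLDS_c + eta * toxicity(p)
                + delta * affinity(c, MoA(p)) + noise.
    """
    cfg = world.config
    rng = _rng(cfg.seed, _S_BASELINE)
    mu0 = rng.normal(cfg.baseline_mean, 1.0, cfg.n_genes)
    expr = (mu0[None, :] + world.cell_offsets.to_numpy()
            + np.outer(world.rho.to_numpy(), world.w.to_numpy())
            + rng.normal(0.0, cfg.baseline_noise, (cfg.n_cells, cfg.n_genes)))
    expression = pd.DataFrame(expr.T, index=world.genes, columns=world.cells)

    tissue_levels = sorted(world.tissue.unique())
    tissue_eff = dict(zip(tissue_levels,
                          rng.normal(0.0, cfg.doubling_tissue_sd,
                                     len(tissue_levels))))
    doubling = (cfg.doubling_time_h
                - cfg.doubling_rho_slope * world.rho
                + world.tissue.map(tissue_eff)
                + rng.normal(0.0, cfg.doubling_noise, cfg.n_cells))
    annotations = pd.DataFrame({
        "tissue": world.tissue, "msi": world.msi,
        "doubling_time_h": doubling,
    })

    tox = drug_toxicity(world)
    rows = []
    noise = rng.normal(0.0, cfg.sensitivity_noise,
                       (cfg.n_cells, cfg.n_compounds))
    ic50_noise = rng.normal(0.0, 0.1, (cfg.n_cells, cfg.n_compounds))
    for ci, c in enumerate(world.cells):
        for pi, p in enumerate(world.compounds):
            auc = (cfg.auc_intercept + world.glds[c]
                   + cfg.sensitivity_potency_scale * tox[p]
                   + cfg.sensitivity_moa_scale
                   * world.cell_moa_affinity.loc[c, world.moa_of[p]]
                   + noise[ci, pi])
            ln_ic50 = (world.log10_ic50.loc[p, c] * np.log(10.0)
                       + ic50_noise[ci, pi])
            rows.append((c, p, auc, ln_ic50))
    sensitivity = pd.DataFrame(rows, columns=["cell_line_id", "drug_id",
                                              "auc", "ln_ic50"])
    return BaselinePanel(expression, annotations, sensitivity)


def simulate_fingerprints(world: SyntheticWorld, n_bits: int | None = None,
                          flip_prob: float = 0.05) -> AnnotationTable:
    """ECFP-like bit vectors: one prototype per MoA class, per-drug bit flips.

    The returned annotation table also carries the MoA label and the maximal
    tested log10 concentration per compound.
    """
    cfg = world.config
    if n_bits is None:
        n_bits = cfg.fingerprint_bits
    rng = _rng(cfg.seed, _S_FINGERPRINT, n_bits)
    prototypes = (rng.random((cfg.n_moa_classes, n_bits)) < 0.3).astype(np.uint8)
    max_log = float(np.log10(max(cfg.doses_um)))
    rows = {}
    for pi, p in enumerate(world.compounds):
        drug_rng = _rng(cfg.seed, _S_FINGERPRINT, n_bits, pi + 1)
        flips = drug_rng.random(n_bits) < flip_prob
        bits = prototypes[world.moa_of[p]] ^ flips.astype(np.uint8)
        rows[p] = {
            "labels": frozenset({world.moa_label(p)}),
            "fingerprint": bits,
            "max_tested_log10_conc": max_log,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "perturbagen_id"
    return AnnotationTable(frame, n_bits=n_bits)


def moa_annotation(world: SyntheticWorld, kind: str = "moa") -> AnnotationTable:
    """Label annotation per compound: MoA class, nominal target, or pathway.

    In this world each MoA class has one nominal target; targeted pathways
    pair a potent class with an inert one, so pathway membership carries no
    toxicity information.
    """
    if kind not in ("moa", "target", "pathway"):
        raise ValueError(f"unknown annotation kind {kind!r}")
    rows = {}
    for p in world.compounds:
        k = world.moa_of[p]
        if kind == "moa":
            label = f"MOA{k:02d}"
        elif kind == "target":
            label = f"TGT{k:02d}"
        else:
            label = f"PW{k // 2:02d}"
        rows[p] = {"labels": frozenset({label})}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "perturbagen_id"
    return AnnotationTable(frame)


def nci60_like_benchmark(world: SyntheticWorld) -> pd.DataFrame:
    """Per (cell, compound) sensitivity metric in NCI60 convention.

    The metric is the log10 concentration reaching the effect (here the
    planted log10 IC50), assigned the maximal tested concentration when the
    effect is not reached within the dose range — so the delta-concentration
    rule (metric minus max tested < 0) flags exactly the compounds whose
    IC50 falls inside the tested range.
    """
    max_log = float(np.log10(max(world.config.doses_um)))
    rows = []
    for p in world.compounds:
        for c in world.cells:
            metric = min(float(world.log10_ic50.loc[p, c]), max_log)
            rows.append((c, p, metric, max_log))
    return pd.DataFrame(rows, columns=["cell_line_id", "perturbagen_id",
                                       "metric_log10_conc",
                                       "max_tested_log10_conc"])
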