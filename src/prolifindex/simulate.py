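"""Synthetic multi-cancer cohort generator with a planted proliferation factor.

The generator emits the full set of inputs the real pipeline consumes — a raw
count matrix, a clinical table, a somatic mutation catalog, a cell-line drug
panel, and a connectivity-style rank matrix — together with the latent truth
that produced them, so every downstream stage can be tested against ground
truth.

Model
-----
Each patient carries a latent proliferation score ``z ~ N(mu_c, 1)`` (``mu_c``
a per-cancer shift) and an independent second latent factor ``w ~ N(0, 1)``.
Counts are negative binomial with mean ``s_i * q_g * exp(beta_g z + delta_g w)``
and gene-wise dispersion ``phi_g``; ``beta_g > 0`` on the designated PI gene
set.  A disjoint second block carries random-sign loadings ``delta_g`` on the
auxiliary factor ``w``, and each cancer owns its own slice of that block, so
auxiliary survival signatures stay unique to each cancer.  Survival is
exponential with hazard ``h0 * exp(gamma_c z + eta_c w)``: ``gamma_c > 0``
exactly in the planted proliferation-informative cancers (PICs), while non-PIC
survival is driven by the cancer's own auxiliary program (random hazard sign).  Censoring is independent
exponential, rate-matched to the configured censoring fraction.  Pathologic
stage tracks ``z`` (plus noise) in PICs only.

Mutation burden is Poisson with log-linear dependence on ``z``; designated
driver genes are mutated with logistic probability in ``z``.  Cell lines carry
their own proliferation surrogate that shifts log-EC50 of "targeted" drugs,
and the rank matrix down-ranks PI probes under anti-proliferative treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import log

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, ValidationError


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world; defaults are the documented scenario."""

    n_cancers: int = 19
    n_pics: int = 7
    n_patients: int = 150          # per cancer
    n_genes: int = 1000
    n_pi_genes: int = 131          # size of the planted proliferation gene set
    n_second_genes: int = 60       # disjoint block loading on the second factor

    beta_low: float = 0.5          # PI-gene loading range on z
    beta_high: float = 1.0
    gamma_pic: float = 0.8         # hazard log-coefficient of z in PICs
    eta_nonpic: float = 0.8        # |hazard coefficient| of w in non-PICs
    aux_fidelity: float = 0.6      # corr between the expressed auxiliary
                                   # program and its survival-relevant facet
                                   # (immune/stromal programs are only partly
                                   # transcriptional)
    mu_spread: float = 0.5         # SD of per-cancer baseline PI shift

    pleiotropy: float = 0.15       # SD of per-(gene, cancer) loading on the
                                   # cancer's auxiliary program: individual
                                   # transcripts carry weak context-dependent
                                   # prognostic signal beyond their main factor
    libsize_sigma: float = 0.25    # LogNormal(0, sigma) library-size factors
    dispersion_low: float = 0.05
    dispersion_high: float = 0.4
    baseline_hazard: float = 1e-3  # events per day
    censoring_rate: float = 0.35

    mutation_intercept: float = log(30.0)  # mean burden ~30 mutations at z=0
    mutation_slope: float = 0.5            # b in Poisson(exp(a + b z))
    n_driver_genes: int = 3
    driver_logit_slope: float = 2.0
    driver_logit_intercept: float = -1.0

    n_lines: int = 486
    n_drugs: int = 24
    n_targeted_drugs: int = 4
    drug_slope: float = 1.0        # tau: log-EC50 decrease per unit z
    ec50_noise: float = 1.0
    n_treatments: int = 60
    n_antiproliferative: int = 5
    n_proproliferative: int = 3
    rank_shift: float = 3.0        # differential-score shift of PI probes

    seed: int = 0

    def validate(self) -> None:
        if self.n_pics > self.n_cancers:
            raise ValidationError("n_pics cannot exceed n_cancers")
        if self.n_pi_genes + self.n_second_genes + self.n_driver_genes > self.n_genes:
            raise ValidationError("gene blocks exceed n_genes")
        for name in ("n_cancers", "n_pics", "n_patients", "n_genes", "n_pi_genes",
                     "n_lines", "n_drugs", "n_treatments"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0, 1)")
        if self.beta_low > self.beta_high:
            raise ValidationError("beta_low > beta_high")


@dataclass
class SyntheticTruth:
    """Planted latent state; the oracle for parameter-recovery tests."""

    z: pd.Series                   # per patient
    w: pd.Series                   # per patient, second factor
    pic_flags: pd.Series           # per cancer, bool
    gamma: pd.Series               # per cancer hazard coefficient on z
    eta: pd.Series                 # per cancer hazard coefficient on w (signed)
    mu: pd.Series                  # per cancer baseline PI shift
    beta: pd.Series                # per gene loading on z
    delta: pd.Series               # per gene loading on w
    q: pd.Series                   # per gene baseline abundance
    phi: pd.Series                 # per gene NB dispersion
    libsize: pd.Series             # per patient library-size factor
    pi_gene_set: GeneSet
    driver_genes: list[str]
    aux_assignment: pd.Series | None = None   # second-block gene -> owning cancer
    targeted_drugs: list[str] = field(default_factory=list)
    antiproliferative_treatments: list[str] = field(default_factory=list)
    proproliferative_treatments: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        flagged = set(self.pic_flags.index[self.pic_flags])
        positive = set(self.gamma.index[self.gamma > 0])
        if flagged != positive:
            raise ValidationError("gamma > 0 must hold exactly for planted PICs")
        if (self.beta.loc[self.pi_gene_set.genes] <= 0).any():
            raise ValidationError("PI-gene loadings must be positive")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent child streams so each generator is deterministic on its own
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def simulate_cohort(cfg: SimulationConfig) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a full multi-cancer cohort: counts, clinical table, and truth."""
    cfg.validate()
    rng = _rng(cfg, 0)

    cancers = [f"C{i + 1:02d}" for i in range(cfg.n_cancers)]
    # a gamma=0 world plants no PICs (null calibration scenario)
    pic_flags = pd.Series([i < cfg.n_pics and cfg.gamma_pic > 0
                           for i in range(cfg.n_cancers)], index=cancers)
    gamma = pd.Series(np.where(pic_flags.values, cfg.gamma_pic, 0.0), index=cancers)
    eta_sign = rng.choice([-1.0, 1.0], size=cfg.n_cancers)
    eta = pd.Series(np.where(pic_flags.values, 0.0, eta_sign * cfg.eta_nonpic), index=cancers)
    mu = pd.Series(rng.normal(0.0, cfg.mu_spread, cfg.n_cancers), index=cancers)

    pi_genes = [f"PIG{i + 1:03d}" for i in range(cfg.n_pi_genes)]
    second_genes = [f"ALT{i + 1:03d}" for i in range(cfg.n_second_genes)]
    n_bg = cfg.n_genes - cfg.n_pi_genes - cfg.n_second_genes
    bg_genes = [f"BKG{i + 1:04d}" for i in range(n_bg)]
    genes = pi_genes + second_genes + bg_genes
    driver_genes = bg_genes[: cfg.n_driver_genes]

    beta = pd.Series(0.0, index=genes)
    beta.loc[pi_genes] = rng.uniform(cfg.beta_low, cfg.beta_high, cfg.n_pi_genes)
    delta = pd.Series(0.0, index=genes)
    # random-sign loadings: a survival-associated program has up- and
    # down-regulated members, and a one-signed block would leak the second
    # factor into size factors (and hence PI) compositionally
    delta.loc[second_genes] = (rng.uniform(cfg.beta_low, cfg.beta_high,
                                           cfg.n_second_genes)
                               * rng.choice([-1.0, 1.0], cfg.n_second_genes))
    # the auxiliary program is cancer-specific: each cancer owns a disjoint
    # slice of the second-factor block, so non-PIC survival signatures stay
    # unique to each cancer (no spurious cross-cancer shared signature)
    aux_assignment = pd.Series(
        [cancers[i % cfg.n_cancers] for i in range(cfg.n_second_genes)],
        index=second_genes)
    q = pd.Series(np.exp(rng.normal(np.log(30.0), 1.0, cfg.n_genes)), index=genes)
    phi = pd.Series(rng.uniform(cfg.dispersion_low, cfg.dispersion_high, cfg.n_genes),
                    index=genes)

    n_total = cfg.n_cancers * cfg.n_patients
    sample_ids = [f"{c}-P{i + 1:04d}" for c in cancers for i in range(cfg.n_patients)]
    cancer_of = np.repeat(cancers, cfg.n_patients)

    z = rng.normal(np.repeat(mu.values, cfg.n_patients), 1.0)
    w = rng.normal(0.0, 1.0, n_total)
    libsize = np.exp(rng.normal(0.0, cfg.libsize_sigma, n_total))

    # negative binomial counts via the gamma-Poisson mixture, genes x samples;
    # second-factor loadings act only on patients of the owning cancer
    log_mean = (np.log(q.values)[:, None]
                + beta.values[:, None] * z[None, :])
    gene_index = pd.Index(genes)
    # weak pleiotropic couplings: every gene responds a little, with a
    # cancer-specific random-sign weight, to that cancer's auxiliary program
    eps = rng.normal(0.0, cfg.pleiotropy, (cfg.n_genes, cfg.n_cancers))
    for ci, cancer in enumerate(cancers):
        cols = np.flatnonzero(cancer_of == cancer)
        log_mean[:, cols] += eps[:, ci][:, None] * w[cols][None, :]
        own = gene_index.get_indexer(aux_assignment.index[aux_assignment == cancer])
        if len(own) and len(cols):
            log_mean[np.ix_(own, cols)] += (delta.values[own][:, None]
                                            * w[cols][None, :])
    mean = libsize[None, :] * np.exp(log_mean)
    shape = (1.0 / phi.values)[:, None]
    lam = rng.gamma(np.broadcast_to(shape, mean.shape), mean / shape)
    counts = rng.poisson(lam).astype(np.int64)

    expr = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids),
                            "raw_counts")

    # exponential survival with log-linear hazard; independent exponential censoring
    gamma_i = gamma.loc[cancer_of].to_numpy()
    eta_i = eta.loc[cancer_of].to_numpy()
    rho = cfg.aux_fidelity
    w_surv = rho * w + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n_total)
    hazard = cfg.baseline_hazard * np.exp(gamma_i * z + eta_i * w_surv)
    t_event = rng.exponential(1.0 / hazard)
    mu_i = mu.loc[cancer_of].to_numpy()
    r = cfg.censoring_rate
    if r > 0:
        # exact rate calibration: an independent exponential censoring time with
        # per-cancer rate lam solving mean_i lam/(lam + h_i) = r
        from scipy.optimize import brentq
        cens_rate = np.empty(n_total)
        for cancer in cancers:
            idx = np.flatnonzero(cancer_of == cancer)
            h = hazard[idx]
            lam = brentq(lambda L: np.mean(L / (L + h)) - r,
                         1e-12 * h.min(), 1e6 * h.max())
            cens_rate[idx] = lam
        t_cens = rng.exponential(1.0 / cens_rate)
    else:
        t_cens = np.full(n_total, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    # pathologic stage follows z (plus unit noise) in PICs, pure noise elsewhere
    is_pic_i = pic_flags.loc[cancer_of].to_numpy()
    stage_driver = np.where(is_pic_i, z - mu_i, rng.normal(0.0, 1.0, n_total))
    stage_score = stage_driver + rng.normal(0.0, 1.0, n_total)
    t_stage = np.digitize(stage_score, [-1.0, 0.0, 1.0]) + 1      # T1..T4
    n_stage = (stage_score + rng.normal(0.0, 0.5, n_total) > 0.3).astype(int)
    m_stage = (stage_score + rng.normal(0.0, 0.5, n_total) > 1.3).astype(int)

    cohort = pd.DataFrame({
        "sample_id": sample_ids,
        "cancer_type": cancer_of,
        "survival_days": time,
        "event": event,
        "stage_T": [f"T{s}" for s in t_stage],
        "stage_N": [f"N{s}" for s in n_stage],
        "stage_M": [f"M{s}" for s in m_stage],
        "subtype": np.nan,
        "purity": np.nan,
    })

    truth = SyntheticTruth(
        z=pd.Series(z, index=sample_ids, name="z"),
        w=pd.Series(w, index=sample_ids, name="w"),
        pic_flags=pic_flags, gamma=gamma, eta=eta, mu=mu,
        beta=beta, delta=delta, q=q, phi=phi,
        libsize=pd.Series(libsize, index=sample_ids, name="libsize"),
        pi_gene_set=GeneSet("planted_pi", pi_genes),
        driver_genes=driver_genes, aux_assignment=aux_assignment, seed=cfg.seed,
    )
    return expr, cohort, truth


def simulate_mutations(truth: SyntheticTruth, cohort: pd.DataFrame,
                       cfg: SimulationConfig) -> pd.DataFrame:
    """Draw a MAF-like somatic mutation catalog coupled to the planted factor.

    Per-patient total burden is ``Poisson(exp(a + b z))`` scattered uniformly
    over the gene universe with class frequencies {missense .5, nonsense .1,
    synonymous .3, other .1}; designated driver genes additionally acquire a
    protein-altering mutation with probability logistic in ``z``.
    """
    if not set(cohort["sample_id"]).issubset(set(truth.z.index)):
        raise ValidationError("cohort sample ids do not match the simulation truth")
    rng = _rng(cfg, 1)
    samples = cohort["sample_id"].to_numpy()
    z = truth.z.loc[samples].to_numpy()
    genes = np.asarray(truth.beta.index)

    counts = rng.poisson(np.exp(cfg.mutation_intercept + cfg.mutation_slope * z))
    total = int(counts.sum())
    rec_samples = np.repeat(samples, counts)
    rec_genes = genes[rng.integers(0, len(genes), total)]
    rec_class = rng.choice(["missense", "nonsense", "synonymous", "other"],
                           size=total, p=[0.5, 0.1, 0.3, 0.1])

    frames = [pd.DataFrame({"sample_id": rec_samples, "gene": rec_genes,
                            "variant_class": rec_class})]
    logit = cfg.driver_logit_intercept + cfg.driver_logit_slope * z
    p_mut = 1.0 / (1.0 + np.exp(-logit))
    # cfg controls how many of the planted driver genes are active here, so a
    # driver-free null catalog can be drawn from the same truth
    for gene in truth.driver_genes[: cfg.n_driver_genes]:
        hit = rng.random(len(samples)) < p_mut
        cls = rng.choice(["missense", "nonsense"], size=int(hit.sum()), p=[0.8, 0.2])
        frames.append(pd.DataFrame({"sample_id": samples[hit], "gene": gene,
                                    "variant_class": cls}))
    return pd.concat(frames, ignore_index=True)


def simulate_drug_panels(truth: SyntheticTruth, cfg: SimulationConfig):
    """Draw a cell-line EC50 panel (with matching expression) and a rank matrix.

    Returns ``(panel, rank_matrix)`` where ``panel`` is a
    :class:`~prolifindex.assoc.DrugResponsePanel` and ``rank_matrix`` a
    :class:`~prolifindex.assoc.TreatmentRankMatrix`.  The planted identities
    (targeted drugs, anti-/pro-proliferative treatments) are recorded on
    ``truth``.
    """
    from .assoc import DrugResponsePanel, TreatmentRankMatrix

    rng = _rng(cfg, 2)
    lines = [f"LINE{i + 1:03d}" for i in range(cfg.n_lines)]
    drugs = [f"drug{i + 1:02d}" for i in range(cfg.n_drugs)]
    targeted = drugs[: cfg.n_targeted_drugs]

    z_l = rng.normal(0.0, 1.0, cfg.n_lines)

    # microarray-like probe expression: 2 probes for every 5th PI gene, 1 otherwise
    probes, probe_gene = [], []
    for g in truth.beta.index:
        probes.append(f"{g}_at")
        probe_gene.append(g)
        if g in set(truth.pi_gene_set.genes[::5]):
            probes.append(f"{g}_x_at")
            probe_gene.append(g)
    probe_gene = pd.Series(probe_gene, index=probes, name="gene")
    beta_p = truth.beta.loc[probe_gene.values].to_numpy()
    base_p = np.log2(truth.q.loc[probe_gene.values].to_numpy())
    expr = (base_p[:, None] + beta_p[:, None] * z_l[None, :]
            + rng.normal(0.0, 0.4, (len(probes), cfg.n_lines)))
    expression = pd.DataFrame(expr, index=probes, columns=lines)

    kappa = rng.uniform(np.log(0.01), np.log(10.0), cfg.n_drugs)
    tau = np.array([cfg.drug_slope if d in targeted else 0.0 for d in drugs])
    log_ec50 = (kappa[None, :] - tau[None, :] * z_l[:, None]
                + rng.normal(0.0, cfg.ec50_noise, (cfg.n_lines, cfg.n_drugs)))
    ec50 = pd.DataFrame(np.exp(log_ec50), index=lines, columns=drugs)

    panel = DrugResponsePanel(ec50=ec50, expression=expression, probe_gene=probe_gene)

    treatments = [f"trt{i + 1:03d}" for i in range(cfg.n_treatments)]
    anti = treatments[: cfg.n_antiproliferative]
    pro = treatments[cfg.n_antiproliferative:
                     cfg.n_antiproliferative + cfg.n_proproliferative]
    pi_probe_mask = probe_gene.isin(truth.pi_gene_set.genes).to_numpy()
    scores = rng.normal(0.0, 1.0, (len(probes), cfg.n_treatments))
    for j, t in enumerate(treatments):
        if t in anti:
            scores[pi_probe_mask, j] -= cfg.rank_shift
        elif t in pro:
            scores[pi_probe_mask, j] += cfg.rank_shift
    # rank 1 = largest positive change
    order = np.argsort(-scores, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(1, len(probes) + 1)
    for j in range(cfg.n_treatments):
        ranks[order[:, j], j] = rows
    rank_df = pd.DataFrame(ranks, index=probes, columns=treatments)
    rank_matrix = TreatmentRankMatrix(ranks=rank_df, probe_gene=probe_gene)

    truth.targeted_drugs = targeted
    truth.antiproliferative_treatments = anti
    truth.proproliferative_treatments = pro
    return panel, rank_matrix


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Flatten the per-patient part of the truth for writing to TSV."""
    return pd.DataFrame({"sample_id": truth.z.index, "z": truth.z.values,
                         "w": truth.w.values})


def config_from_dict(d: dict) -> SimulationConfig:
    cfg = SimulationConfig(**d)
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)
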