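"""Synthetic cohorts and GWAS summary statistics with known ground truth.

Two generator families live here:

* :func:`generate_cohort` builds aligned individual-level tables (brain
  network measures, ordinal questionnaire items, three-window activity
  summaries, confounds) whose population canonical correlations between
  blocks are *exactly* the requested values.  The construction plants shared
  latent factors with loading norms solved in closed form from the target
  correlations, so :func:`population_canonical_correlations` provides an
  analytic oracle for recovery tests.

* :func:`generate_sumstats` / :func:`generate_multitrait_sumstats` draw
  per-SNP Z-scores obeying the LD-score regression moment model
  ``Var(Z_ij) = intercept + N_i h2_i l_j / M`` and
  ``Cov(Z_1j, Z_2j) = sqrt(N1 N2) rho_g l_j / M + overlap``, optionally
  routing effects through a heavy-tailed latent mediator so that causal
  architecture (genetic causality proportion) is identifiable downstream.

Design notes
------------
Cross-block structure: with orthonormal within-block directions and unit
idiosyncratic noise, a latent shared with coefficient ``a`` on both sides
yields canonical correlation ``rho = a^2 / (a^2 + 1)``; hence
``a = sqrt(rho / (1 - rho))`` plants ``rho`` exactly.  The activity block is
emitted as three correlated window replicates of 7 base measures, which
*raises* the canonical correlation of the 21-column block relative to a
single replicate; base loadings are therefore solved against the
window-adjusted expression so the full block's canonical correlations still
equal the target.

Confound effects enter all blocks linearly and independently of the shared
latents, so the planted canonical correlations describe the
confound-residualized (and, for questionnaire items, pre-discretization)
structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .tables import PhenotypeTable

PA_MEASURES = ("sleep", "sedentary", "light", "moderate", "walking",
               "overall", "met")
PA_WINDOWS = ("overall", "weekday", "weekend")

CONFOUND_KINDS = {
    "age": "continuous", "sex": "categorical", "site": "categorical",
    "smoking": "categorical", "drinking": "categorical",
    "bmi": "continuous", "motion": "continuous", "timegap": "continuous",
}

DEFAULT_CONFOUND_EFFECTS = {
    "age": 0.10, "sex": 0.10, "site": 0.05, "smoking": 0.05,
    "drinking": 0.05, "bmi": 0.10, "motion": 0.05, "timegap": 0.02,
}


# ======================================================================
# cohort generation
# ======================================================================

@dataclass
class CohortConfig:
    """Parameters of the individual-level generative model."""

    n_subjects: int = 6000
    canonical_rhos: tuple[float, ...] = (0.25, 0.15)
    n_latents: int | None = None          # defaults to len(canonical_rhos)
    n_subnets: int = 7                    # -> C(7,2)=21 edges + 7 amplitudes
    n_mh_items: int = 31
    n_pa_base: int = 7                    # replicated over 3 windows -> 21
    window_corr: float = 0.8
    cross_block_mode: str = "independent"  # or "shared" (full mediation)
    item_thresholds: tuple[float, ...] | None = (-1.0, 0.0, 1.0)
    missing_rate: float | dict[str, float] = 0.0
    missing_mechanism: str = "MCAR"        # or "MAR-on-confound" (age)
    mar_strength: float = 1.0
    confound_missing_rate: float = 0.0
    confound_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUND_EFFECTS))
    seed: int = 0

    def __post_init__(self) -> None:
        rhos = np.asarray(self.canonical_rhos, dtype=float)
        if rhos.size and (np.any(rhos < 0) or np.any(rhos >= 1)):
            raise ValueError("canonical_rhos must lie in [0, 1)")
        if np.any(np.diff(rhos) > 1e-12):
            raise ValueError("canonical_rhos must be non-increasing")
        if self.n_latents is None:
            self.n_latents = len(rhos)
        if self.n_latents < len(rhos):
            raise ValueError("n_latents must be >= len(canonical_rhos)")
        rates = (self.missing_rate.values()
                 if isinstance(self.missing_rate, dict)
                 else [self.missing_rate])
        for r in rates:
            if not 0 <= r <= 0.95:
                raise ValueError("missing_rate must be within [0, 0.95]")
        if self.missing_mechanism not in ("MCAR", "MAR-on-confound"):
            raise ValueError(f"unknown mechanism {self.missing_mechanism!r}")
        if self.cross_block_mode not in ("independent", "shared"):
            raise ValueError(f"unknown mode {self.cross_block_mode!r}")

    @property
    def n_brain(self) -> int:
        k = self.n_subnets
        return k * (k - 1) // 2 + k

    @property
    def n_pa(self) -> int:
        return self.n_pa_base * len(PA_WINDOWS)

    def rho_vector(self) -> np.ndarray:
        rhos = np.zeros(self.n_latents)
        rhos[: len(self.canonical_rhos)] = self.canonical_rhos
        return rhos


@dataclass
class Cohort:
    """Aligned synthetic tables plus the generative ground truth."""

    brain: PhenotypeTable
    mh_items: PhenotypeTable
    pa: PhenotypeTable
    confounds: PhenotypeTable
    truth: dict

    def tables(self) -> dict[str, PhenotypeTable]:
        return {"brain": self.brain, "mh_items": self.mh_items,
                "pa": self.pa, "confounds": self.confounds}


def brain_column_names(n_subnets: int) -> list[str]:
    pairs = itertools.combinations(range(1, n_subnets + 1), 2)
    edges = [f"edge_net{i}-net{j}" for i, j in pairs]
    amps = [f"amp_net{i}" for i in range(1, n_subnets + 1)]
    return edges + amps


def pa_column_names(n_base: int) -> list[str]:
    measures = (PA_MEASURES if n_base == len(PA_MEASURES)
                else tuple(f"pa{i + 1}" for i in range(n_base)))
    return [f"{m}_{w}" for w in PA_WINDOWS for m in measures]


def _window_gamma(window_corr: float) -> float:
    return (1.0 - window_corr) / len(PA_WINDOWS)


def _mh_loading(rho: float) -> float:
    # rho = a^2 / (a^2 + 1) with equal coefficients on both sides
    return float(np.sqrt(rho / (1.0 - rho)))


def _pa_loading_symmetric(rho: float, window_corr: float) -> float:
    """Equal brain/base coefficient giving canonical rho for the window block."""
    if rho == 0:
        return 0.0
    w, g = window_corr, _window_gamma(window_corr)

    def f(a2: float) -> float:
        return w * a2 ** 2 - rho ** 2 * (a2 + 1) * (w * (a2 + 1) + g)

    hi = 4.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError(f"canonical rho {rho} infeasible for PA block")
    a2 = optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    return float(np.sqrt(a2))


def _pa_loading_given_brain(rho: float, c: float, window_corr: float) -> float:
    """Base coefficient when the brain-side coefficient ``c`` is fixed."""
    if rho == 0:
        return 0.0
    w, g = window_corr, _window_gamma(window_corr)
    # closed form: p^2 = rho (w + g) / (w (1 - rho)) when c^2 = rho/(1-rho)
    num = rho ** 2 * (c ** 2 + 1) * (w + g)
    den = w * (c ** 2 - rho ** 2 * (c ** 2 + 1))
    if den <= 0:
        raise ValueError(f"canonical rho {rho} infeasible given brain loading")
    return float(np.sqrt(num / den))


def _orthonormal(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n_rows, n_cols)))
    return q[:, :n_cols]


def _loading_matrices(config: CohortConfig, rng: np.random.Generator):
    """Latent loading matrices (brain, mh, pa_base) over the joint latent space.

    Independent mode uses 2K latents (first K shared brain<->MH, last K shared
    brain<->PA); shared mode uses K latents common to all three blocks.
    """
    k = config.n_latents
    rhos = config.rho_vector()
    p, m, b = config.n_brain, config.n_mh_items, config.n_pa_base
    shared = config.cross_block_mode == "shared"
    d = k if shared else 2 * k

    for dim, label in ((p, "brain"), (m, "mh_items"), (b, "pa base")):
        need = d if label == "brain" else k
        if dim < need:
            bad = int(np.argmax(np.arange(k) >= dim)) if dim < k else 0
            raise ValueError(
                f"canonical_rhos[{bad}] infeasible: {label} block rank {dim} "
                f"< required latent dimension {need}")

    a_mh = np.array([_mh_loading(r) for r in rhos])
    u_brain = _orthonormal(rng, p, d)
    v_mh = _orthonormal(rng, m, k)
    v_pa = _orthonormal(rng, b, k)

    lam_brain = np.zeros((p, d))
    lam_mh = np.zeros((m, d))
    lam_pa = np.zeros((b, d))
    if shared:
        a_pa = np.array([_pa_loading_given_brain(r, c, config.window_corr)
                         for r, c in zip(rhos, a_mh)])
        lam_brain = u_brain * a_mh
        lam_mh[:, :k] = v_mh * a_mh
        lam_pa[:, :k] = v_pa * a_pa
    else:
        a_pa = np.array([_pa_loading_symmetric(r, config.window_corr)
                         for r in rhos])
        lam_brain[:, :k] = u_brain[:, :k] * a_mh
        lam_brain[:, k:] = u_brain[:, k:] * a_pa
        lam_mh[:, :k] = v_mh * a_mh
        lam_pa[:, k:] = v_pa * a_pa
    return lam_brain, lam_mh, lam_pa


def analytic_covariance(config: CohortConfig):
    """Exact joint covariance over [brain | MH underliers | PA window block].

    Excludes confound effects and questionnaire discretization (both are
    removed/attenuating transforms applied after this structure).
    Returns ``(sigma, slices)`` with a slice per block.
    """
    rng = np.random.default_rng(config.seed)
    lam_brain, lam_mh, lam_pa = _loading_matrices(config, rng)
    w = config.window_corr
    n_win = len(PA_WINDOWS)
    lam_pa_full = np.sqrt(w) * np.tile(lam_pa, (n_win, 1))
    lam = np.vstack([lam_brain, lam_mh, lam_pa_full])

    p, m, q = config.n_brain, config.n_mh_items, config.n_pa
    psi = np.eye(p + m + q)
    # window noise: shared base noise (cov w) + window-specific (1 - w)
    pa_noise = (np.kron(np.ones((n_win, n_win)), w * np.eye(config.n_pa_base))
                + (1 - w) * np.eye(q))
    psi[p + m:, p + m:] = pa_noise
    sigma = lam @ lam.T + psi
    slices = {"brain": slice(0, p), "mh": slice(p, p + m),
              "pa": slice(p + m, p + m + q)}
    return sigma, slices


def population_canonical_correlations(
        config: CohortConfig, pair: tuple[str, str] = ("brain", "pa"),
) -> np.ndarray:
    """Analytic canonical correlations between two blocks of the model.

    Computes singular values of ``Syy^{-1/2} Syx Sxx^{-1/2}`` on the exact
    joint covariance, descending.  Serves as the oracle for recovery tests.
    """
    sigma, slices = analytic_covariance(config)
    sa, sb = slices[pair[0]], slices[pair[1]]
    saa = sigma[sa, sa]
    sbb = sigma[sb, sb]
    sab = sigma[sa, sb]
    for name, s in ((pair[0], saa), (pair[1], sbb)):
        if np.linalg.cond(s) > 1e12:
            raise ValueError(f"within-block covariance of {name!r} is singular")
    wa = _inv_sqrt(saa)
    wb = _inv_sqrt(sbb)
    sv = np.linalg.svd(wa @ sab @ wb, compute_uv=False)
    return np.sort(np.clip(sv, 0, 1))[::-1]


def _inv_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() <= 0:
        raise ValueError("covariance block not positive definite")
    return vecs @ np.diag(vals ** -0.5) @ vecs.T


def _draw_confounds(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    df = pd.DataFrame(index=pd.RangeIndex(n, name="subject"))
    df["age"] = 63.7 + 7.5 * rng.standard_normal(n)
    df["sex"] = rng.integers(0, 2, n).astype(float)
    df["site"] = rng.integers(0, 3, n).astype(float)
    df["smoking"] = rng.choice(3, n, p=[0.55, 0.30, 0.15]).astype(float)
    df["drinking"] = rng.choice(3, n, p=[0.25, 0.55, 0.20]).astype(float)
    df["bmi"] = 27.0 + 4.0 * rng.standard_normal(n)
    df["motion"] = np.exp(0.4 * rng.standard_normal(n) - 2.0)
    df["timegap"] = rng.normal(200.0, 120.0, n)
    return df


def _confound_signal(config: CohortConfig, conf: pd.DataFrame) -> np.ndarray:
    """Summed linear confound effect (one common signal, z-scored inputs)."""
    total = np.zeros(len(conf))
    for name, effect in config.confound_effects.items():
        if effect == 0 or name not in conf.columns:
            continue
        x = conf[name].to_numpy(dtype=float)
        x = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        total += effect * x
    return total


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw aligned brain / questionnaire / activity / confound tables.

    The same seed reproduces tables bit-for-bit.  Ground-truth parameters
    (loading matrices, planted canonical correlations) are stored in
    ``cohort.truth`` and in each table's metadata.
    """
    rng = np.random.default_rng(config.seed)
    lam_brain, lam_mh, lam_pa = _loading_matrices(config, rng)
    n = config.n_subjects
    d = lam_brain.shape[1]

    g = rng.standard_normal((n, d))
    brain = g @ lam_brain.T + rng.standard_normal((n, config.n_brain))
    mh_raw = g @ lam_mh.T + rng.standard_normal((n, config.n_mh_items))
    pa_base = g @ lam_pa.T + rng.standard_normal((n, config.n_pa_base))

    w = config.window_corr
    pa_cols = []
    for _ in PA_WINDOWS:
        eps = rng.standard_normal((n, config.n_pa_base))
        pa_cols.append(np.sqrt(w) * pa_base + np.sqrt(1 - w) * eps)
    pa = np.hstack(pa_cols)

    conf_df = _draw_confounds(config, rng)
    signal = _confound_signal(config, conf_df)
    brain = brain + signal[:, None]
    mh_raw = mh_raw + signal[:, None]
    pa = pa + signal[:, None]

    # discretize questionnaire items at the configured cut-points
    if config.item_thresholds is not None:
        thresholds = np.asarray(config.item_thresholds, dtype=float)
        mh = np.digitize(mh_raw, thresholds).astype(float)
        mh_kind = "ordinal"
        levels = list(range(len(thresholds) + 1))
    else:
        mh = mh_raw
        mh_kind = "continuous"
        levels = None

    # missingness on questionnaire items
    idx = conf_df.index
    mh_df = pd.DataFrame(
        mh, index=idx,
        columns=[f"item{i + 1:02d}" for i in range(config.n_mh_items)])
    rates = config.missing_rate
    if not isinstance(rates, dict):
        rates = {c: config.missing_rate for c in mh_df.columns}
    age_z = ((conf_df["age"] - conf_df["age"].mean())
             / conf_df["age"].std()).to_numpy()
    for col, rate in rates.items():
        if rate <= 0 or col not in mh_df.columns:
            continue
        if config.missing_mechanism == "MCAR":
            p_miss = np.full(n, rate)
        else:  # MAR conditioned on age through a logistic link
            logit = np.log(rate / (1 - rate)) + config.mar_strength * age_z
            p_miss = 1.0 / (1.0 + np.exp(-logit))
        mh_df.loc[rng.uniform(size=n) < p_miss, col] = np.nan

    if config.confound_missing_rate > 0:
        for col in ("bmi", "smoking", "drinking"):
            mask = rng.uniform(size=n) < config.confound_missing_rate
            conf_df.loc[mask, col] = np.nan

    truth = {
        "canonical_rhos": list(config.canonical_rhos),
        "cross_block_mode": config.cross_block_mode,
        "seed": config.seed,
        "loadings_brain": lam_brain, "loadings_mh": lam_mh,
        "loadings_pa_base": lam_pa, "window_corr": w,
        "latents": g,
    }
    meta = {"canonical_rhos": list(config.canonical_rhos),
            "cross_block_mode": config.cross_block_mode, "seed": config.seed}

    brain_t = PhenotypeTable(
        pd.DataFrame(brain, index=idx,
                     columns=brain_column_names(config.n_subnets)),
        meta=dict(meta))
    mh_t = PhenotypeTable(
        mh_df, kinds={c: mh_kind for c in mh_df.columns},
        meta=dict(meta, levels=levels))
    pa_t = PhenotypeTable(
        pd.DataFrame(pa, index=idx, columns=pa_column_names(config.n_pa_base)),
        meta=dict(meta))
    conf_t = PhenotypeTable(conf_df, kinds=dict(CONFOUND_KINDS), meta=dict(meta))
    return Cohort(brain_t, mh_t, pa_t, conf_t, truth)


# ======================================================================
# summary statistics generation
# ======================================================================

@dataclass
class SumStatsConfig:
    """Parameters of the two-trait GWAS summary-statistic generator."""

    m_snps: int = 50_000
    n1: int = 100_000
    n2: int = 100_000
    h2_1: float = 0.10
    h2_2: float = 0.10
    rho_g: float = 0.0                 # genetic covariance; rg = rho_g/sqrt(h2 h2)
    sample_overlap_intercept: float = 0.0
    ld_shape: float = 2.0
    ld_scale: float = 20.0
    lcv_mode: str = "none"             # none | pleiotropy | causal_1to2 | causal_2to1
    q1: float | None = None            # normalized latent loadings
    q2: float | None = None
    pi_prob: float = 0.05              # mixture mass of the heavy-tailed latent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps <= 0:
            raise ValueError("M must be positive")
        for h2 in (self.h2_1, self.h2_2):
            if not 0 <= h2 <= 1:
                raise ValueError("h2 must lie in [0, 1]")
        if self.h2_1 > 0 and self.h2_2 > 0:
            rg = self.rho_g / np.sqrt(self.h2_1 * self.h2_2)
            if abs(rg) > 1 + 1e-12:
                raise ValueError(f"implied rg {rg:.3f} outside [-1, 1]")
        if self.lcv_mode not in ("none", "pleiotropy", "causal_1to2",
                                 "causal_2to1"):
            raise ValueError(f"unknown lcv_mode {self.lcv_mode!r}")

    def rg(self) -> float:
        if self.h2_1 == 0 or self.h2_2 == 0:
            return 0.0
        return self.rho_g / np.sqrt(self.h2_1 * self.h2_2)


def _snp_frame(z: np.ndarray, n: int, labels: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"SNP": labels, "A1": "A", "A2": "G",
                         "Z": z, "N": n})


def _draw_ld_scores(config: SumStatsConfig, rng: np.random.Generator) -> np.ndarray:
    return 1.0 + rng.gamma(config.ld_shape, config.ld_scale, config.m_snps)


def _latent_loadings(config: SumStatsConfig) -> tuple[float, float]:
    rg = config.rg()
    if config.q1 is not None and config.q2 is not None:
        return float(config.q1), float(config.q2)
    if config.lcv_mode == "pleiotropy":
        root = float(np.sqrt(abs(rg)))
        return root, float(np.sign(rg) * root) if rg != 0 else root
    if config.lcv_mode == "causal_1to2":
        return 1.0, rg
    if config.lcv_mode == "causal_2to1":
        return rg, 1.0
    raise ValueError("latent loadings only defined for lcv_mode != 'none'")


def generate_sumstats(config: SumStatsConfig):
    """Draw a pair of summary-statistic tables plus the matching LD scores.

    Returns ``((ss1, ss2), ld)`` where each element of the pair is a
    DataFrame with columns SNP, A1, A2, Z, N and ``ld`` is a DataFrame with
    SNP, L2 (and ``ld.attrs['m_total']`` = M).
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    ld = _draw_ld_scores(config, rng)
    labels = np.array([f"rs{i + 1}" for i in range(m)])
    s = ld / m  # per-SNP effect-variance profile

    if config.lcv_mode == "none":
        var1 = 1.0 + config.n1 * config.h2_1 * s
        var2 = 1.0 + config.n2 * config.h2_2 * s
        cov = (np.sqrt(config.n1 * config.n2) * config.rho_g * s
               + config.sample_overlap_intercept)
        bad = cov ** 2 > var1 * var2
        if np.any(bad):
            j = int(np.argmax(bad))
            raise ValueError(
                f"per-SNP Z covariance not positive semi-definite at SNP {j}")
        z1 = rng.standard_normal(m) * np.sqrt(var1)
        resid_sd = np.sqrt(np.maximum(var2 - cov ** 2 / var1, 0.0))
        z2 = cov / var1 * z1 + rng.standard_normal(m) * resid_sd
    else:
        q1, q2 = _latent_loadings(config)
        if max(abs(q1), abs(q2)) > 1 + 1e-12:
            raise ValueError("latent loadings must lie in [-1, 1]")
        p0 = config.pi_prob
        # heavy-tailed latent: point-normal mixture, Var(pi_j) = s_j
        active = rng.uniform(size=m) < p0
        pi = np.where(active,
                      rng.standard_normal(m) * np.sqrt(s / p0), 0.0)
        d1 = rng.standard_normal(m) * np.sqrt((1 - q1 ** 2) * s)
        d2 = rng.standard_normal(m) * np.sqrt((1 - q2 ** 2) * s)
        a1 = np.sqrt(config.h2_1) * (q1 * pi + d1)
        a2 = np.sqrt(config.h2_2) * (q2 * pi + d2)
        rho_e = config.sample_overlap_intercept
        e1 = rng.standard_normal(m)
        e2 = rho_e * e1 + np.sqrt(max(1 - rho_e ** 2, 0.0)) * rng.standard_normal(m)
        z1 = np.sqrt(config.n1) * a1 + e1
        z2 = np.sqrt(config.n2) * a2 + e2

    ss1 = _snp_frame(z1, config.n1, labels)
    ss2 = _snp_frame(z2, config.n2, labels)
    ld_df = pd.DataFrame({"SNP": labels, "L2": ld})
    ld_df.attrs["m_total"] = m
    return (ss1, ss2), ld_df


def generate_multitrait_sumstats(
        h2: np.ndarray, rg_matrix: np.ndarray, n_samples: np.ndarray,
        m_snps: int, seed: int = 0, ld_shape: float = 2.0,
        ld_scale: float = 20.0, overlap: np.ndarray | None = None,
        labels: list[str] | None = None):
    """Joint summary statistics for P traits with a given genetic correlation
    matrix (e.g. a one-factor structure ``rg = lam lam' + diag(1 - lam^2)``).

    Returns ``(list of sumstats DataFrames, ld DataFrame)``.
    """
    h2 = np.asarray(h2, dtype=float)
    rg_matrix = np.asarray(rg_matrix, dtype=float)
    n_samples = np.asarray(n_samples, dtype=int)
    p = len(h2)
    if rg_matrix.shape != (p, p):
        raise ValueError("rg_matrix shape mismatch")
    vals = np.linalg.eigvalsh(rg_matrix)
    if vals.min() < -1e-8:
        raise ValueError("rg_matrix not positive semi-definite")
    rng = np.random.default_rng(seed)
    ld = 1.0 + rng.gamma(ld_shape, ld_scale, m_snps)
    s = ld / m_snps
    snp_labels = np.array([f"rs{i + 1}" for i in range(m_snps)])

    root = linalg.cholesky(rg_matrix + 1e-10 * np.eye(p), lower=True)
    alpha = rng.standard_normal((m_snps, p)) @ root.T       # corr = rg_matrix
    a = alpha * np.sqrt(s)[:, None] * np.sqrt(h2)[None, :]
    if overlap is None:
        e = rng.standard_normal((m_snps, p))
    else:
        e_root = linalg.cholesky(np.asarray(overlap) + 1e-10 * np.eye(p),
                                 lower=True)
        e = rng.standard_normal((m_snps, p)) @ e_root.T
    z = np.sqrt(n_samples)[None, :] * a + e

    frames = [_snp_frame(z[:, i], int(n_samples[i]), snp_labels)
              for i in range(p)]
    if labels is not None:
        for f, lab in zip(frames, labels):
            f.attrs["label"] = lab
    ld_df = pd.DataFrame({"SNP": snp_labels, "L2": ld})
    ld_df.attrs["m_total"] = m_snps
    return frames, ld_df


# ----------------------------------------------------------------------
# text I/O for the sumstats / LD-score dialects
# ----------------------------------------------------------------------

def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    required = {"SNP", "A1", "A2", "Z", "N"}
    if not required.issubset(df.columns):
        raise ValueError(f"sumstats file missing columns {required - set(df.columns)}")
    return df


def write_ld_scores(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t", index=False)


def read_ld_scores(path, m_total: int | None = None) -> pd.DataFrame:
    ld = pd.read_csv(path, sep="\t")
    if not {"SNP", "L2"}.issubset(ld.columns):
        raise ValueError("LD-score file must have columns SNP, L2")
    ld.attrs["m_total"] = m_total if m_total is not None else len(ld)
    return ld
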