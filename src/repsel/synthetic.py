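"""Generative model of the mating-group experiment.

Each focal carries latent quality effects on the log (mating rate) and
log-odds (sperm and paternity share) scales; groups add independent noise
on the same scales, and batches shift partner fecundity. Counts are then
Poisson/Binomial, so all invariants of the observation tables hold by
construction, and the implied "true" repeatability of any component can be
obtained by brute-force simulation at large n.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_data, fitness
from .io_data import Dataset
from .repeatability import TRANSFORMS, icc_anova
from .types import COMPONENTS, GROUP_LABELS, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of the generative model (defaults emulate the study's scale)."""

    n_focals: int = 150
    n_groups: int = 3
    n_partners: int = 4
    n_batches: int = 8
    mating_rate: float = 6.0  # Poisson rate per dyad over the trial
    sigma_ms: float = 0.0  # focal latent SD, log mating-rate scale
    sigma_ste: float = 0.0  # focal latent SD, log-odds sperm-share scale
    sigma_sfe: float = 0.0  # focal latent SD, log-odds paternity-share scale
    tau_ms: float = 0.0  # group-level noise SDs, same scales
    tau_ste: float = 0.0
    tau_sfe: float = 0.0
    sperm_pool_mean: float = 21.0  # Poisson mean stored sperm per partner
    fecundity_mean: float = 5.8  # Poisson mean offspring per partner
    sigma_batch_f: float = 0.0  # batch effect SD on log fecundity
    egg_prob: float = 0.0  # P(egg in antrum -> total sperm unobservable)
    penetrance: float = 1.0
    penetrance_screen_mean: float = 48.0
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_ms", "sigma_ste", "sigma_sfe", "tau_ms", "tau_ste",
                     "tau_sfe", "sigma_batch_f", "penetrance_screen_mean"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("mating_rate", "sperm_pool_mean", "fecundity_mean"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("egg_prob", "penetrance"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.n_groups > len(GROUP_LABELS):
            raise ValidationError(f"at most {len(GROUP_LABELS)} groups supported")


@dataclass
class TruthRecord:
    """Latent effects and generative-truth summaries stored with a dataset."""

    latent_ms: np.ndarray
    latent_ste: np.ndarray
    latent_sfe: np.ndarray
    config: SimulationConfig
    true_icc: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "latent_ms": self.latent_ms.tolist(),
            "latent_ste": self.latent_ste.tolist(),
            "latent_sfe": self.latent_sfe.tolist(),
            "config": asdict(self.config),
            "true_icc": self.true_icc,
        }


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_counts(cfg: SimulationConfig, rng: np.random.Generator, n_focals: int):
    """Core count arrays; shapes (n_focals, n_groups[, n_partners])."""
    nf, ng, npart = n_focals, cfg.n_groups, cfg.n_partners
    a = rng.normal(0, cfg.sigma_ms, nf)
    b = rng.normal(0, cfg.sigma_ste, nf)
    c = rng.normal(0, cfg.sigma_sfe, nf)
    eps = rng.normal(0, cfg.tau_ms, (nf, ng))
    eta = rng.normal(0, cfg.tau_ste, (nf, ng))
    nu = rng.normal(0, cfg.tau_sfe, (nf, ng))
    batch = np.arange(nf) % cfg.n_batches
    beta = rng.normal(0, cfg.sigma_batch_f, cfg.n_batches)

    # 10 dyads in a 5-worm group: npart involve the focal, the rest do not
    n_other_dyads = (npart + 1) * npart // 2 - npart
    focal_rate = cfg.mating_rate * np.exp(a[:, None] + eps)
    m_focal = rng.poisson(focal_rate[:, :, None], (nf, ng, npart)).sum(axis=2)
    m_other = rng.poisson(cfg.mating_rate, (nf, ng, n_other_dyads)).sum(axis=2)
    m_total = m_focal + m_other

    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(m_total > 0, m_focal / np.maximum(m_total, 1), 0.0)
    half = 0.5 / np.maximum(m_total, 1)
    share_c = np.clip(share, half, 1 - half)
    p_sperm = np.where(
        m_focal > 0, _logistic(_logit(share_c) + b[:, None] + eta), 0.0
    )

    # no copulations in a group -> nothing stored in any of its recipients
    s_total = rng.poisson(cfg.sperm_pool_mean, (nf, ng, npart))
    s_total = np.where(m_total[:, :, None] > 0, s_total, 0)
    s_focal = rng.binomial(s_total, p_sperm[:, :, None])

    with np.errstate(divide="ignore", invalid="ignore"):
        sshare = np.where(s_total > 0, s_focal / np.maximum(s_total, 1), 0.0)
    half_s = 0.5 / np.maximum(s_total, 1)
    sshare_c = np.clip(sshare, half_s, 1 - half_s)
    p_off = np.where(
        s_focal > 0,
        _logistic(_logit(sshare_c) + c[:, None, None] + nu[:, :, None]),
        0.0,
    )
    # offspring require received sperm
    o_total = rng.poisson(cfg.fecundity_mean * np.exp(beta[batch])[:, None, None],
                          (nf, ng, npart))
    o_total = np.where(s_total > 0, o_total, 0)
    o_focal = rng.binomial(o_total, p_off)

    return {
        "latents": (a, b, c),
        "batch": batch + 1,
        "m_total": m_total,
        "m_focal": m_focal,
        "s_total": s_total,
        "s_focal": s_focal,
        "o_total": o_total,
        "o_focal": o_focal,
    }


def simulate_dataset(cfg: SimulationConfig, compute_truth_icc: bool = False):
    """Simulate one experiment; same seed gives a bit-identical dataset.

    Returns (:class:`~repsel.io_data.Dataset`, :class:`TruthRecord`).
    Egg-in-antrum recipients have their total-sperm count masked exactly as
    in the real data (focal sperm stay countable).
    """
    rng = np.random.default_rng(cfg.seed)
    sim = _simulate_counts(cfg, rng, cfg.n_focals)
    nf, ng, npart = cfg.n_focals, cfg.n_groups, cfg.n_partners
    labels = list(GROUP_LABELS[:ng])
    width = max(3, len(str(nf)))
    ids = np.array([f"R{i + 1:0{width}d}" for i in range(nf)])

    groups = pd.DataFrame({
        "replicate_id": np.repeat(ids, ng),
        "batch": np.repeat(sim["batch"], ng),
        "group_label": np.tile(labels, nf),
        "total_matings": sim["m_total"].reshape(-1),
        "focal_matings": sim["m_focal"].reshape(-1),
    })

    egg = rng.random((nf, ng, npart)) < cfg.egg_prob
    total_sperm = sim["s_total"].astype(float)
    total_sperm[egg] = np.nan
    recipients = pd.DataFrame({
        "replicate_id": np.repeat(ids, ng * npart),
        "group_label": np.tile(np.repeat(labels, npart), nf),
        "recipient_index": np.tile(np.arange(1, npart + 1), nf * ng),
        "total_sperm": total_sperm.reshape(-1),
        "focal_sperm": sim["s_focal"].reshape(-1),
        "egg_in_antrum": egg.reshape(-1),
        "total_offspring": sim["o_total"].reshape(-1),
        "focal_offspring": sim["o_focal"].reshape(-1),
    })

    screened = rng.poisson(cfg.penetrance_screen_mean, nf)
    positive = rng.binomial(screened, cfg.penetrance)
    penetrance = pd.DataFrame({
        "replicate_id": ids,
        "offspring_screened": screened,
        "gfp_positive": positive,
    })

    a, b, c = sim["latents"]
    truth = TruthRecord(latent_ms=a, latent_ste=b, latent_sfe=c, config=cfg)
    if compute_truth_icc:
        truth.true_icc = {comp: true_icc(cfg, comp) for comp in COMPONENTS}
    return Dataset(groups, recipients, penetrance), truth


def per_group_components_from_counts(sim: dict) -> Dict[str, np.ndarray]:
    """Per-focal x group component values straight from count arrays."""
    m_t = sim["m_total"].astype(float)
    m_f = sim["m_focal"].astype(float)
    s_t = sim["s_total"].sum(axis=2).astype(float)
    s_f = sim["s_focal"].sum(axis=2).astype(float)
    o_t = sim["o_total"].sum(axis=2).astype(float)
    o_f = sim["o_focal"].sum(axis=2).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(m_t > 0, m_f / m_t, np.nan)
        sperm_share = np.where(s_t > 0, s_f / s_t, np.nan)
        off_share = np.where(o_t > 0, o_f / o_t, np.nan)
        ste = np.where((m_f > 0) & (s_t > 0), sperm_share / ms, np.nan)
        sfe = np.where((s_f > 0) & (o_t > 0), off_share / sperm_share, np.nan)
    return {"F": o_t, "MS": ms, "STE": ste, "SFE": sfe, "mRS": o_f}


def true_icc(
    cfg: SimulationConfig,
    component: str,
    n_focals: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """Large-sample ICC of the transformed per-group component.

    This is the operational definition of the generative model's "true"
    repeatability: brute-force simulation at large n, one-way ANOVA ICC on
    the transformed values (egg masking off -- measurement imputation is an
    estimation-side effect, not part of the generative truth).
    """
    rng = np.random.default_rng(cfg.seed + 987_654_321 if seed is None else seed)
    sim = _simulate_counts(cfg, rng, n_focals)
    comps = per_group_components_from_counts(sim)
    x = comps[component]
    with np.errstate(invalid="ignore"):
        t = TRANSFORMS[component](x)
    codes = np.repeat(np.arange(n_focals), cfg.n_groups)
    flat = t.reshape(-1)
    ok = ~np.isnan(flat)
    return icc_anova(flat[ok], pd.factorize(codes[ok])[0])[0]


def recovery_experiment(
    grid: Sequence[SimulationConfig],
    n_sims: int = 20,
    boot_iterations: int = 200,
    seed: int = 0,
    components: Sequence[str] = COMPONENTS,
    truth_n: int = 50_000,
) -> pd.DataFrame:
    """Simulate each config repeatedly, run the pipeline, compare to truth.

    For every config cell: the true ICC per component (brute force), the
    mean and RMSE of the estimated repeatability over ``n_sims``
    simulations, the coverage of the bootstrap R CI, and the rate at which
    the I_R interval includes zero. Pipeline errors are recorded per cell,
    never fatal.
    """
    from .ir_metric import compute_ir
    from .variance import BootstrapConfig

    rows = []
    for ci, cfg in enumerate(grid):
        truths = {c: true_icc(cfg, c, n_focals=truth_n, seed=seed + 17 * ci)
                  for c in components}
        est = {c: [] for c in components}
        cover = {c: 0 for c in components}
        ir_zero = {c: 0 for c in components}
        n_err = 0
        n_ok = 0
        for s in range(n_sims):
            run_cfg = SimulationConfig(**{**asdict(cfg), "seed": seed + 1000 * ci + s})
            try:
                ds, _ = simulate_dataset(run_cfg)
                bcfg = BootstrapConfig(iterations=boot_iterations,
                                       seed=seed + 1000 * ci + s)
                table = compute_ir(ds, bcfg, r_method="anova")
            except Exception as exc:  # recorded, not fatal
                logger.warning("recovery cell %d sim %d failed: %s", ci, s, exc)
                n_err += 1
                continue
            n_ok += 1
            for c in components:
                row = table.rows[c]
                est[c].append(row.R)
                if row.R_ci[0] <= truths[c] <= row.R_ci[1]:
                    cover[c] += 1
                if row.IR_pct_ci[0] <= 0:
                    ir_zero[c] += 1
        for c in components:
            e = np.asarray(est[c], dtype=float)
            rows.append({
                "config_index": ci,
                "component": c,
                "true_R": truths[c],
                "n_sims_ok": n_ok,
                "n_sims_failed": n_err,
                "mean_R": float(np.nanmean(e)) if e.size else np.nan,
                "bias": float(np.nanmean(e) - truths[c]) if e.size else np.nan,
                "rmse": float(np.sqrt(np.nanmean((e - truths[c]) ** 2))) if e.size else np.nan,
                "R_ci_coverage": cover[c] / n_ok if n_ok else np.nan,
                "IR_ci_covers_zero": ir_zero[c] / n_ok if n_ok else np.nan,
            })
    return pd.DataFrame(rows)
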