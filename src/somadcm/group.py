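"""Group-level random-effects Bayesian model selection and averaging.

Per analysis window, subjects' free energies feed a variational Dirichlet
scheme over model frequencies (random-effects BMS): the model identity is
treated as varying across subjects, and the posterior Dirichlet yields
expected model frequencies and exceedance probabilities (EP) -- the
probability that each model is more frequent in the population than every
competitor.  EPs sum to one over the model set.

Bayesian model averaging (BMA) summarizes thalamic input strengths across
subjects -- by default restricted to the group-level winning model -- and a
paired t-test contrasts the input strength into SI against that into SII.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .inversion import InversionSettings, PosteriorDensity, invert, window_data
from .model_space import AnalysisPlan, WindowSpec

__all__ = [
    "EvidenceTable",
    "DirichletPosterior",
    "GroupResult",
    "rfx_bms",
    "exceedance",
    "bma_inputs",
    "sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class EvidenceTable:
    """Free energies per subject and model for one window (nats)."""

    values: np.ndarray               # (n_subjects, n_models)
    subject_ids: tuple
    model_labels: tuple
    window: WindowSpec | None = None
    accuracy: np.ndarray | None = None     # same shape as values, optional
    complexity: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x models)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 models")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free energies must be finite")


@dataclass
class DirichletPosterior:
    """Posterior over model frequencies r ~ Dirichlet(alpha)."""

    alpha: np.ndarray
    exceedance_prob: np.ndarray
    model_labels: tuple = ()

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive")
        self.exceedance_prob = np.asarray(self.exceedance_prob, dtype=float)

    @property
    def expected_freq(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()


@dataclass
class GroupResult:
    """BMA input-strength summaries and the SI-vs-SII contrast."""

    si_strength: np.ndarray          # per subject
    sii_strength: np.ndarray
    mean_ratio: float                # mean SI / mean SII strength
    t: float
    df: int
    p: float
    mode: str = "winning"


def rfx_bms(ev: EvidenceTable, alpha0: np.ndarray | None = None,
            n_samples: int = 1_000_000, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 500) -> DirichletPosterior:
    """Variational random-effects BMS over the table's model set.

    Iterates the posterior model assignments g_nk and the Dirichlet counts
    alpha_k = alpha0_k + sum_n g_nk to convergence, then computes exceedance
    probabilities (closed form for two models, Monte Carlo otherwise).
    """
    F = ev.values
    n_sub, n_mod = F.shape
    alpha0 = np.ones(n_mod) if alpha0 is None else np.asarray(alpha0, float)
    # per-subject max subtraction guards the exp against overflow
    F = F - F.max(axis=1, keepdims=True)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        logu = F + special.digamma(alpha) - special.digamma(alpha.sum())
        logu = logu - logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.linalg.norm(alpha_new - alpha) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    ep = exceedance(alpha, n_samples=n_samples, seed=seed)
    return DirichletPosterior(alpha=alpha, exceedance_prob=ep,
                              model_labels=ev.model_labels)


def exceedance(alpha: np.ndarray, n_samples: int = 1_000_000,
               seed: int = 0, method: str = "auto") -> np.ndarray:
    """P(r_k > r_j for all j != k) under Dirichlet(alpha).

    Exact Beta closed form for two models; seeded Monte Carlo otherwise
    (the argmax partition makes the estimate sum to one exactly).
    ``method`` forces one route: 'auto', 'exact' (two models only), 'mc'.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if method not in ("auto", "exact", "mc"):
        raise ValueError("method must be 'auto', 'exact' or 'mc'")
    if method == "exact" and alpha.size != 2:
        raise ValueError("closed form requires exactly two models")
    if alpha.size == 2 and method != "mc":
        # r1 > r2  <=>  r1 > 1/2 with r1 ~ Beta(a1, a2)
        p1 = 1.0 - stats.beta.cdf(0.5, alpha[0], alpha[1])
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    counts = np.zeros(alpha.size)
    chunk = 200_000
    left = int(n_samples)
    while left > 0:
        n = min(chunk, left)
        r = rng.dirichlet(alpha, size=n)
        idx, c = np.unique(np.argmax(r, axis=1), return_counts=True)
        counts[idx] += c
        left -= n
    return counts / n_samples


def _input_strengths(post: PosteriorDensity) -> tuple:
    """Total posterior input strength into SIc and into SIIc.

    Amplitude parameters are log-scales of prior-mean gains; strengths are
    summed over components on the natural scale."""
    si = sii = 0.0
    for k, name in enumerate(post.names):
        if name.startswith("amp_") and name.endswith("_SIc"):
            si += float(np.exp(post.mean[k]))
        elif name.startswith("amp_") and name.endswith("_SIIc"):
            sii += float(np.exp(post.mean[k]))
    return si, sii


def bma_inputs(ev: EvidenceTable, posteriors, mode: str = "winning"
               ) -> GroupResult:
    """Input-strength contrast (SI vs SII) after model averaging.

    ``posteriors[n][k]`` is the PosteriorDensity of subject n under model k.
    ``mode='winning'`` restricts averaging to the group-level winning model
    (one-hot weights); ``mode='softmax'`` weights each subject's models by
    the softmax of their free energies.  Subjects' SI and SII strengths are
    compared by a paired two-sided t-test.
    """
    F = ev.values
    n_sub, n_mod = F.shape
    if n_sub < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    if mode == "winning":
        k_win = int(np.argmax(F.sum(axis=0)))
        weights = np.zeros_like(F)
        weights[:, k_win] = 1.0
    elif mode == "softmax":
        z = F - F.max(axis=1, keepdims=True)
        weights = np.exp(z)
        weights /= weights.sum(axis=1, keepdims=True)
    else:
        raise ValueError("mode must be 'winning' or 'softmax'")
    si = np.zeros(n_sub)
    sii = np.zeros(n_sub)
    for n in range(n_sub):
        for k in range(n_mod):
            if weights[n, k] == 0:
                continue
            s1, s2 = _input_strengths(posteriors[n][k])
            si[n] += weights[n, k] * s1
            sii[n] += weights[n, k] * s2
    diff = si - sii
    if np.allclose(diff, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(si, sii)
    ratio = float(si.mean() / sii.mean()) if sii.mean() != 0 else np.inf
    return GroupResult(si_strength=si, sii_strength=sii, mean_ratio=ratio,
                       t=float(t), df=n_sub - 1, p=float(p), mode=mode)


def sweep(plan: AnalysisPlan, subjects, priors=None,
          settings: InversionSettings | None = None,
          n_modes: int = 7, seed: int = 0,
          keep_posteriors: bool = False):
    """Invert every (subject, model) cell for every window and run RFX BMS.

    ``subjects`` is a sequence of ``(erf, gain)`` pairs.  A failed inversion
    is logged and the subject is excluded from that window's BMS.  Returns a
    list of ``(WindowSpec, DirichletPosterior)``; with ``keep_posteriors``
    the per-window ``(EvidenceTable, posteriors)`` are returned as a third
    element per entry.
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    st = settings or InversionSettings()
    results = []
    for w_i, window in enumerate(plan.windows):
        F = np.full((len(subjects), len(plan.models)), np.nan)
        A = np.full_like(F, np.nan)
        C = np.full_like(F, np.nan)
        posts = [[None] * len(plan.models) for _ in subjects]
        for n, (erf, gain) in enumerate(subjects):
            try:
                rd = window_data(erf, window, gain, n_modes=n_modes)
            except ValueError as e:
                logger.warning("subject %d window %s: %s", n, window, e)
                continue
            for k, model in enumerate(plan.models):
                prior = None if priors is None else priors[k]
                try:
                    post, evd = invert(model, rd, prior=prior, settings=st,
                                       estimate_timing=plan.estimate_timing)
                except (FloatingPointError, RuntimeError,
                        np.linalg.LinAlgError) as e:
                    logger.warning(
                        "inversion failed (subject %d, model %s, window %s):"
                        " %s", n, plan.model_labels[k], window, e)
                    continue
                F[n, k] = evd.free_energy
                A[n, k] = evd.accuracy
                C[n, k] = evd.complexity
                posts[n][k] = post
        ok = np.all(np.isfinite(F), axis=1)
        if ok.sum() < 2:
            raise RuntimeError(f"fewer than 2 complete subjects for {window}")
        ev = EvidenceTable(values=F[ok],
                           subject_ids=tuple(str(i) for i in np.nonzero(ok)[0]),
                           model_labels=tuple(plan.model_labels),
                           window=window, accuracy=A[ok], complexity=C[ok])
        dp = rfx_bms(ev, seed=seed + w_i)
        if keep_posteriors:
            posts_ok = [posts[i] for i in np.nonzero(ok)[0]]
            results.append((window, dp, (ev, posts_ok)))
        else:
            results.append((window, dp))
    return results
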