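"""Mixed-stock analysis: EM estimation of stock proportions and the
simulation machinery around it.

Mixture proportions are estimated by conditional maximum likelihood:
baseline allele frequencies per reporting unit are held fixed (posterior
mean (x + 1/2)/(n + 1), matching the assignment module's per-allele 1/2
prior) and EM alternates computing per-fish origin responsibilities and
updating the proportion vector.  The log-likelihood is non-decreasing
across iterations — a property the tests assert.

Simulation replicates propagate baseline sampling uncertainty by drawing
unit allele frequencies from the Dirichlet (here Beta) posterior of the
observed counts, regenerating a baseline sample of the same gene counts
from one draw, and generating the mixture genotypes from an independent
second draw — so mixture fish are never scored against frequencies
fitted to their own realized genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import MISSING, AlleleCountTable, BaselineHierarchy, GenotypeMatrix
from .simulate import MixtureTruth, simulate_mixture

logger = logging.getLogger(__name__)


@dataclass
class MixtureEstimate:
    """EM result: proportions on the simplex plus convergence diagnostics."""

    units: list[str]
    pi: np.ndarray
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    n_excluded: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.pi, index=self.units, name="pi_hat")


def _hwe_logprobs(freqs: np.ndarray) -> np.ndarray:
    """(U, L, 3) log genotype probabilities under HWE at given frequencies."""
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore"):
        lf, l1f = np.log(f), np.log(1.0 - f)
        return np.stack([2 * l1f, np.log(2.0) + lf + l1f, 2 * lf], axis=-1)


def mixture_loglik_matrix(codes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """(M fish x U units) HWE genotype log-likelihoods; missing loci skipped."""
    lp = _hwe_logprobs(freqs)
    M = codes.shape[0]
    ll = np.zeros((M, freqs.shape[0]))
    impossible = np.zeros((M, freqs.shape[0]), dtype=bool)
    for g in range(3):
        mask = (codes == g).astype(float)
        lpg = lp[:, :, g].T.copy()           # (L, U)
        bad = ~np.isfinite(lpg)
        lpg[bad] = 0.0
        ll += mask @ lpg
        impossible |= (mask @ bad.astype(float)) > 0
    ll[impossible] = -np.inf
    return ll


def em_mixture(mix: GenotypeMatrix | np.ndarray, unit_freqs: dict[str, np.ndarray],
               tol: float = 1e-8, max_iter: int = 5000,
               start: np.ndarray | None = None) -> MixtureEstimate:
    """Conditional-ML mixture proportions by EM from a uniform start.

    ``unit_freqs`` maps unit -> per-locus A-allele frequency on the
    mixture's loci.  Fish with zero likelihood in every unit (possible
    when a unit frequency is exactly 0/1) are excluded with a warning.
    Stops when max|delta pi| < tol.
    """
    codes = mix.codes if isinstance(mix, GenotypeMatrix) else np.asarray(mix)
    if codes.shape[0] < 1:
        raise ValueError("empty mixture")
    units = sorted(unit_freqs)
    freqs = np.vstack([unit_freqs[u] for u in units])
    ll = mixture_loglik_matrix(codes, freqs)        # (M, U)
    usable = np.isfinite(ll.max(axis=1))
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.warning("em_mixture: excluding %d fish with zero likelihood "
                       "in every unit", n_excluded)
        ll = ll[usable]
    if ll.shape[0] == 0:
        raise ValueError("no usable mixture fish")
    M, U = ll.shape
    pi = np.full(U, 1.0 / U) if start is None else np.asarray(start, float)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            log_wt = ll + np.log(pi)
        norm = logsumexp(log_wt, axis=1)
        trace.append(float(norm.sum()))
        resp = np.exp(log_wt - norm[:, None])
        pi_new = resp.mean(axis=0)
        delta = np.abs(pi_new - pi).max()
        pi = pi_new
        if delta < tol:
            converged = True
            break
    return MixtureEstimate(units, pi, trace, converged, it, n_excluded)


def draw_realization(counts: AlleleCountTable, rng: np.random.Generator):
    """One parametric-resampling replicate of the baseline.

    Per unit/locus, draws a frequency from the Beta(x_A + 1/2, x_B + 1/2)
    posterior, regenerates a baseline sample with the *same gene counts*
    from that draw, and independently draws a second frequency for
    generating mixture genotypes.  Returns (simulated AlleleCountTable,
    mixture frequency array (U, L)).  The regenerated table is
    allele-level only: heterozygote counts are not tracked because the
    mixture likelihood needs allele frequencies alone.
    """
    xa = counts.n_a.astype(float)
    xb = counts.n_b.astype(float)
    n = counts.n
    f_base = rng.beta(xa + 0.5, xb + 0.5)
    f_mix = rng.beta(xa + 0.5, xb + 0.5)
    new_xa = rng.binomial(n, f_base)
    sim = AlleleCountTable(list(counts.groups), list(counts.locus_ids),
                           new_xa, n - new_xa,
                           np.zeros_like(new_xa), counts.n_ind,
                           counts.grouping)
    return sim, f_mix


@dataclass
class SimulationSummary:
    """Replicate distribution of the estimated proportions per unit."""

    table: pd.DataFrame       # unit, truth, mean, lo, hi, se
    estimates: pd.DataFrame   # B x units matrix of pi-hat
    B: int
    mix_size: int


def _summarize(estimates: pd.DataFrame, truth: pd.Series, mix_size: int
               ) -> SimulationSummary:
    B = len(estimates)
    table = pd.DataFrame({
        "truth": truth,
        "mean": estimates.mean(axis=0),
        "lo": estimates.quantile(0.025, axis=0),
        "hi": estimates.quantile(0.975, axis=0),
        "se": estimates.std(axis=0, ddof=1) / np.sqrt(B),
    })
    table.index.name = "unit"
    return SimulationSummary(table, estimates, B, mix_size)


def _one_replicate(counts, pi, mix_size, seed):
    rng = np.random.default_rng(seed)
    sim_counts, f_mix = draw_realization(counts, rng)
    unit_freq_mix = {u: f_mix[i] for i, u in enumerate(sim_counts.groups)}
    mix_gm, _ = simulate_mixture(unit_freq_mix, pi, mix_size,
                                 int(rng.integers(2 ** 31)),
                                 locus_ids=list(counts.locus_ids))
    ref = {u: sim_counts.posterior_mean_frequencies()[i]
           for i, u in enumerate(sim_counts.groups)}
    return em_mixture(mix_gm, ref)


def sim_100pct(counts: AlleleCountTable, B: int = 1000, mix_size: int = 200,
               seed: int = 0) -> dict[str, SimulationSummary]:
    """100% simulations: each replicate's mixture is drawn entirely from one
    unit and estimated against the full (regenerated) baseline.

    Returns one SimulationSummary per unit; the headline number per unit
    is the mean estimated proportion of the true (sole) unit.
    """
    units = sorted(counts.groups)
    if len(units) < 2:
        raise ValueError("need >= 2 units")
    root = np.random.default_rng(seed)
    out: dict[str, SimulationSummary] = {}
    for u in units:
        pi = {v: (1.0 if v == u else 0.0) for v in units}
        rows = []
        for b in range(B):
            est = _one_replicate(counts, pi, mix_size,
                                 int(root.integers(2 ** 31)))
            rows.append(est.as_series())
        estimates = pd.DataFrame(rows).reset_index(drop=True)
        truth = pd.Series({v: pi[v] for v in estimates.columns})
        out[u] = _summarize(estimates, truth, mix_size)
    return out


def sim_fishery(counts: AlleleCountTable, pi_true, B: int = 1000,
                mix_size: int = 1000, seed: int = 0) -> SimulationSummary:
    """Realistic fishery simulation at a known composition.

    ``pi_true`` is a dict unit -> proportion (or an array over the sorted
    units) summing to 1; supports equal proportions or catch-derived
    vectors.  Reports mean, 95% percentile CI over replicates, and the
    standard error of the mean.
    """
    units = sorted(counts.groups)
    if isinstance(pi_true, dict):
        if sorted(pi_true) != units:
            raise ValueError("pi_true units do not match baseline units")
        pi = {u: float(pi_true[u]) for u in units}
    else:
        arr = np.asarray(pi_true, dtype=float)
        if arr.size != len(units):
            raise ValueError("pi_true length does not match number of units")
        pi = dict(zip(units, arr))
    root = np.random.default_rng(seed)
    rows = []
    for b in range(B):
        est = _one_replicate(counts, pi, mix_size, int(root.integers(2 ** 31)))
        rows.append(est.as_series())
    estimates = pd.DataFrame(rows).reset_index(drop=True)
    truth = pd.Series({u: pi[u] for u in estimates.columns})
    return _summarize(estimates, truth, mix_size)


def unit_frequencies(counts: AlleleCountTable) -> dict[str, np.ndarray]:
    """Posterior-mean allele frequencies per unit, for mixture generation."""
    pm = counts.posterior_mean_frequencies()
    return {u: pm[i] for i, u in enumerate(counts.groups)}
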