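"""Heterogeneous EIF/rEIF parameter populations via a Gaussian copula.

Generates parameter sets for each pyramidal-cell class (L2/3, L4,
slender-tufted L5, thick-tufted L5) that respect both the empirical
marginal distributions and the parameter covariance structure.  Sampling is
a Gaussian copula: each log-normally distributed parameter is mapped to its
logarithm, the transformed vector (log C, log tau, E, V_T, log Delta_T) is
drawn from a multivariate normal with the empirical transformed-space
covariance, and log members are exponentiated back.

Marginals are specified on the natural scale as (mu, sigma); log-normal
members are converted to log-space moments by exact moment matching

    s^2 = ln(1 + (sigma/mu)^2),   m = ln(mu) - s^2/2.

The post-spike block (g1, tau_g, V_T1, tau_T plus the E dynamics) is drawn
independently of the EIF block and component-wise independently, because no
empirical covariance for it is tabulated; a covariance can be supplied via
``ClassPopulationSpec.postspike_cov`` to override this default.  Each cell
gets a sag indicator Bernoulli(sag_fraction): sag cells receive
bi-exponential E dynamics obtained by drawing the summary quadruple
(E_jump, E_sag, t_sag, t_0) and inverting it to (E1, E2, tau_E1, tau_E2);
no-sag cells draw a mono-exponential (E_mono, tau_mono) from a single
class-independent distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_model import (
    EIFParams,
    InfeasibleSummaryError,
    PostSpikeSummary,
    RefractoryDynamics,
    invert_E_summary,
    rEIFParams,
)

__all__ = [
    "MarginalSpec",
    "ClassPopulationSpec",
    "CLASS_NAMES",
    "lognormal_to_transformed",
    "transformed_to_lognormal",
    "builtin_class_spec",
    "generate_eif_population",
    "generate_reif_population",
    "fit_marginal",
    "cohort_statistics",
]

CLASS_NAMES = ("L23", "L4", "SL5", "TL5")

EIF_ORDER = ("C", "tau", "E", "V_T", "Delta_T")
POSTSPIKE_ORDER = ("g1", "tau_g", "V_T1", "tau_T")
SUMMARY_ORDER = ("E_jump", "E_sag", "t_sag", "t_0")


def lognormal_to_transformed(mu: float, sigma: float) -> tuple[float, float]:
    """Natural-scale (mean, SD) of a log-normal -> (log-mean, log-SD).

    Exact moment matching: s^2 = ln(1 + (sigma/mu)^2), m = ln mu - s^2/2.
    """
    if mu <= 0:
        raise ValueError("log-normal natural mean must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    s2 = math.log1p((sigma / mu) ** 2)
    m = math.log(mu) - s2 / 2.0
    return m, math.sqrt(s2)


def transformed_to_lognormal(m: float, s: float) -> tuple[float, float]:
    """Inverse of :func:`lognormal_to_transformed`."""
    mu = math.exp(m + s * s / 2.0)
    sigma = mu * math.sqrt(math.expm1(s * s))
    return mu, sigma


@dataclass(frozen=True)
class MarginalSpec:
    """One parameter's marginal distribution, natural-scale moments."""

    name: str
    family: str
    mu: float
    sigma: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.family == "lognormal" and self.mu <= 0:
            raise ValueError("lognormal mean must be positive")

    @property
    def is_log(self) -> bool:
        return self.family == "lognormal"

    def transformed_moments(self) -> tuple[float, float]:
        """(mean, SD) in the copula's transformed (sampling) space."""
        if self.is_log:
            return lognormal_to_transformed(self.mu, self.sigma)
        return self.mu, self.sigma

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        m, s = self.transformed_moments()
        z = m + s * rng.standard_normal(n)
        return np.exp(z) if self.is_log else z


@dataclass(frozen=True)
class ClassPopulationSpec:
    """Per-class population statistics driving the generator."""

    class_name: str
    eif_marginals: dict
    eif_cov: np.ndarray
    postspike_marginals: dict
    sag_fraction: float
    mono_fallback: dict
    eif_spearman_lower: Optional[list] = None
    postspike_cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.eif_cov, dtype=float)
        object.__setattr__(self, "eif_cov", cov)
        if cov.shape != (len(EIF_ORDER),) * 2:
            raise ValueError("eif_cov must be 5x5")
        if not np.allclose(cov, cov.T):
            raise ValueError("eif_cov must be symmetric")
        # fail at spec load, not at sampling
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("eif_cov is not positive definite") from exc
        if not 0.0 <= self.sag_fraction <= 1.0:
            raise ValueError("sag_fraction must lie in [0, 1]")
        if self.postspike_cov is not None:
            pcov = np.asarray(self.postspike_cov, dtype=float)
            object.__setattr__(self, "postspike_cov", pcov)
            np.linalg.cholesky(pcov)


def _marginals_from_dict(d: dict) -> dict:
    return {
        name: MarginalSpec(name=name, **{k: v for k, v in m.items()})
        for name, m in d.items()
    }


def _load_builtin() -> dict:
    with resources.files("reifpop.data").joinpath("class_specs.json").open() as fh:
        return json.load(fh)


_BUILTIN_CACHE: dict = {}


def builtin_class_spec(class_name: str) -> ClassPopulationSpec:
    """The built-in empirical population spec for one cell class."""
    if class_name not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_name!r}; choose from {CLASS_NAMES}")
    if class_name not in _BUILTIN_CACHE:
        raw = _load_builtin()
        cls = raw["classes"][class_name]
        _BUILTIN_CACHE[class_name] = ClassPopulationSpec(
            class_name=class_name,
            eif_marginals=_marginals_from_dict(cls["eif_marginals"]),
            eif_cov=np.array(cls["eif_cov"]),
            postspike_marginals=_marginals_from_dict(cls["postspike_marginals"]),
            sag_fraction=cls["sag_fraction"],
            mono_fallback=_marginals_from_dict(raw["mono_fallback"]),
            eif_spearman_lower=cls.get("eif_spearman_lower"),
        )
    return _BUILTIN_CACHE[class_name]


def spec_from_dict(d: dict, class_name: str = "custom") -> ClassPopulationSpec:
    """Build a spec from a plain dict (e.g. loaded from a user JSON/YAML file)."""
    return ClassPopulationSpec(
        class_name=d.get("class_name", class_name),
        eif_marginals=_marginals_from_dict(d["eif_marginals"]),
        eif_cov=np.array(d["eif_cov"]),
        postspike_marginals=_marginals_from_dict(d["postspike_marginals"]),
        sag_fraction=d["sag_fraction"],
        mono_fallback=_marginals_from_dict(d["mono_fallback"]),
        eif_spearman_lower=d.get("eif_spearman_lower"),
        postspike_cov=np.array(d["postspike_cov"]) if d.get("postspike_cov") is not None else None,
    )


MAX_REJECTION_ROUNDS = 100


def _draw_eif_block(
    spec: ClassPopulationSpec, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Draw n valid EIF parameter rows (columns in EIF_ORDER, natural scale).

    Draws the transformed-space multivariate normal, exponentiates the log
    members and reject-resamples rows violating the EIFParams invariants
    (V_T > E; positivity is automatic for log members).  Returns the rows
    and the number of rejected draws.
    """
    margs = [spec.eif_marginals[k] for k in EIF_ORDER]
    mean = np.array([m.transformed_moments()[0] for m in margs])
    is_log = np.array([m.is_log for m in margs])
    chol = np.linalg.cholesky(spec.eif_cov)

    out = np.empty((n, len(EIF_ORDER)))
    filled = 0
    rejected = 0
    rounds = 0
    while filled < n:
        need = n - filled
        z = mean + rng.standard_normal((need, len(EIF_ORDER))) @ chol.T
        x = np.where(is_log, np.exp(z), z)
        ok = x[:, EIF_ORDER.index("V_T")] > x[:, EIF_ORDER.index("E")]
        k = int(ok.sum())
        out[filled : filled + k] = x[ok]
        filled += k
        rejected += need - k
        rounds += 1
        if rounds > MAX_REJECTION_ROUNDS:
            raise RuntimeError("rejection sampling failed to converge")
    return out, rejected


def generate_eif_population(
    spec: ClassPopulationSpec, n: int, seed: int = 0
) -> list[EIFParams]:
    """Sample ``n`` EIF parameter sets with the spec's marginals and covariance."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    rows, _ = _draw_eif_block(spec, n, rng)
    return [
        EIFParams(C=r[0], tau=r[1], E=r[2], V_T=r[3], Delta_T=r[4]) for r in rows
    ]


MAX_SAG_ATTEMPTS = 100


def _draw_sag_dynamics(
    spec: ClassPopulationSpec, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Draw a feasible bi-exponential E parameterisation for one sag cell.

    Draws the summary quadruple from its log-normal marginals and inverts
    it; infeasible summaries (no bi-exponential realises them, including
    draws with t_0 >= t_sag) are resampled, capped at MAX_SAG_ATTEMPTS.
    """
    margs = {k: spec.postspike_marginals[k] for k in SUMMARY_ORDER}
    for _ in range(MAX_SAG_ATTEMPTS):
        vals = {k: float(m.sample(1, rng)[0]) for k, m in margs.items()}
        s = PostSpikeSummary(
            E_jump=vals["E_jump"], has_sag=True, E_sag=vals["E_sag"],
            t_sag=vals["t_sag"], t_0=vals["t_0"],
        )
        try:
            return invert_E_summary(s)
        except InfeasibleSummaryError:
            continue
    raise RuntimeError(
        f"no feasible sag summary found in {MAX_SAG_ATTEMPTS} attempts for "
        f"class {spec.class_name}"
    )


def generate_reif_population(
    spec: ClassPopulationSpec, n: int, seed: int = 0
) -> list[rEIFParams]:
    """Sample ``n`` full rEIF parameter sets.

    EIF block as in :func:`generate_eif_population`; post-spike jumps and
    decay constants drawn log-normally; the E dynamics are bi-exponential
    with probability ``sag_fraction`` (via summary inversion) and
    mono-exponential from the class-independent fallback otherwise.  The
    reset voltage is left at its default (the steady-state threshold).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    rows, _ = _draw_eif_block(spec, n, rng)
    post = {k: spec.postspike_marginals[k].sample(n, rng) for k in POSTSPIKE_ORDER}
    sag = rng.random(n) < spec.sag_fraction

    cells = []
    for i in range(n):
        eif = EIFParams(
            C=rows[i, 0], tau=rows[i, 1], E=rows[i, 2], V_T=rows[i, 3], Delta_T=rows[i, 4]
        )
        common = dict(
            g1=float(post["g1"][i]), tau_g=float(post["tau_g"][i]),
            V_T1=float(post["V_T1"][i]), tau_T=float(post["tau_T"][i]),
        )
        if sag[i]:
            E1, E2, tau_E1, tau_E2 = _draw_sag_dynamics(spec, rng)
            refr = RefractoryDynamics(
                E_mode="bi", E1=E1, E2=E2, tau_E1=tau_E1, tau_E2=tau_E2, **common
            )
        else:
            e_mono = float(spec.mono_fallback["E_mono"].sample(1, rng)[0])
            tau_mono = float(spec.mono_fallback["tau_mono"].sample(1, rng)[0])
            refr = RefractoryDynamics(
                E_mode="mono", E_mono=e_mono, tau_mono=tau_mono, **common
            )
        cells.append(rEIFParams(eif=eif, refractory=refr))
    return cells


def fit_marginal(samples: Sequence[float], family_hint: Optional[str] = None) -> MarginalSpec:
    """Method-of-moments fit of a normal or log-normal marginal.

    Without a hint the family is chosen by the higher maximised Gaussian
    log-likelihood (on the raw vs. the log scale, with the Jacobian).
    Returns natural-scale (mu, sigma).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    mu, sigma = float(np.mean(x)), float(np.std(x, ddof=1))
    family = family_hint
    if family is None:
        if sigma == 0.0:
            family = "normal"
        elif np.any(x <= 0):
            family = "normal"
        else:
            ll_norm = np.sum(stats.norm.logpdf(x, mu, sigma))
            lx = np.log(x)
            ll_logn = np.sum(
                stats.norm.logpdf(lx, lx.mean(), lx.std(ddof=1)) - lx
            )
            family = "lognormal" if ll_logn > ll_norm else "normal"
    if family == "lognormal" and np.any(x <= 0):
        raise ValueError("log-normal family requires positive samples")
    return MarginalSpec(name="fitted", family=family, mu=mu, sigma=sigma)


def _transformed_matrix(params: Sequence, block: str = "eif") -> tuple[np.ndarray, list]:
    """Stack cells into the transformed space used by the copula."""
    names = []
    cols = []
    first = params[0]
    eifs = [p.eif if isinstance(p, rEIFParams) else p for p in params]
    for k in EIF_ORDER:
        m = [getattr(e, k) for e in eifs]
        if k in ("C", "tau", "Delta_T"):
            cols.append(np.log(m))
            names.append(f"log_{k}")
        else:
            cols.append(np.array(m, dtype=float))
            names.append(k)
    if block == "full" and isinstance(first, rEIFParams):
        for k in POSTSPIKE_ORDER:
            m = np.array([getattr(p.refractory, k) for p in params], dtype=float)
            cols.append(np.log(m))
            names.append(f"log_{k}")
    return np.column_stack(cols), names


def cohort_statistics(params: Sequence, block: str = "eif"):
    """Transformed-space covariance and Spearman matrices of a cohort.

    ``block='eif'`` uses (log C, log tau, E, V_T, log Delta_T); with
    ``block='full'`` on rEIF cells the log post-spike jump/decay columns are
    appended.  Used to validate generated cohorts against the empirical
    covariance tables.  Returns ``(cov, spearman, names)``.
    """
    if len(params) < 3:
        raise ValueError("need at least 3 cells")
    X, names = _transformed_matrix(params, block=block)
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("degenerate (zero-variance) parameter column")
    cov = np.cov(X, rowvar=False)
    rho = stats.spearmanr(X).statistic
    if np.ndim(rho) == 0:  # only possible with 2 columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    return cov, rho, names
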