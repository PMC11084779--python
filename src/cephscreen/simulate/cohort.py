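"""Synthetic tabular cohorts emulating the reference screening population.

The generator draws a latent multivariate normal over all directly measured
parameters and maps each latent column through its marginal distribution
(a Gaussian copula). Most marginals are plain normals with the reference
mean/SD. The two outcome parameters ``A_min`` and ``V_PAS`` use two-component
normal-mixture marginals solved so that three constraints hold exactly in
distribution: the reference mean, the reference SD, and the outcome
prevalence at the clinical threshold (P(A_min < 80 mm^2) = 0.30,
P(V_PAS < 12 cm^3) = 0.32). A single normal cannot satisfy all three (it
implies prevalences of 0.24/0.26); the real parameters are right-skewed.

Pearson correlations are requested on the *observed* scale. Because a
monotone marginal transform attenuates Pearson correlation by the factor
``lambda = corr(Z, T(Z))``, the latent correlations are pre-corrected
(divided by lambda for normal-vs-transformed pairs; solved numerically for
the transformed-vs-transformed pair), so requested correlations are
recovered on the output scale.

A correlation matrix assembled from pairwise targets need not be positive
semi-definite (the reference targets are not); it is repaired by eigenvalue
clipping and the effective matrix is reported in ``DataFrame.attrs``.

Derived columns — ANB = SNA - SNB, Sum = NSAr + SArGo + ArGoMe, the two
face-height ratios, and BMI = BW / (BH/100)^2 — are computed from their
parents so the record-level identities hold in every synthetic table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .. import reference
from ..errors import InvalidSpecError

#: Columns drawn on the latent normal (everything else is derived).
DRAWN_COLUMNS = tuple(
    p for p in reference.PARAMETER_STATS if p not in reference.DERIVED_PARAMETERS
)

#: Final column order of a generated cohort table.
COHORT_COLUMNS = reference.ALL_PARAMETERS + ("age", "gender", "BH", "BW", "BMI")

_GH_NODES = 96  # Gauss-Hermite resolution for copula moment integrals


def nearest_psd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest positive semi-definite correlation matrix by eigenvalue clipping."""
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= eps:
        return corr
    w = np.clip(w, eps, None)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


# --------------------------------------------------------------------------
# marginal distributions
# --------------------------------------------------------------------------

class _NormalMarginal:
    """Plain normal marginal: x = mean + sd * z."""

    lam = 1.0  # no Pearson attenuation

    def __init__(self, mean: float, sd: float):
        self.mean, self.sd = float(mean), float(sd)

    def transform(self, z: np.ndarray) -> np.ndarray:
        return self.mean + self.sd * z


class _MixtureMarginal:
    """Two-component normal mixture matched to (mean, sd, threshold quantile).

    Component weights equal the target prevalence ``p``; the narrow first
    component (SD fixed at sd/5, mirroring the affected subgroup's spread in
    the reference cohort) sits low, the broad second component high, and the
    three free parameters (m1, m2, s2) are solved so the mixture has the
    requested mean and SD and puts exactly ``p`` probability below the
    clinical threshold.
    """

    def __init__(self, mean: float, sd: float, threshold: float, p: float):
        self.mean, self.sd = float(mean), float(sd)
        self.threshold, self.p = float(threshold), float(p)
        self.w = self.p
        self.s1 = self.sd / 5.0
        self._solve()
        self._build_quantile_table()
        self.lam = self._attenuation()

    def _equations(self, x):
        m1, m2, s2 = x
        w, s1 = self.w, self.s1
        mean = w * m1 + (1 - w) * m2
        second = w * (s1**2 + m1**2) + (1 - w) * (s2**2 + m2**2)
        cdf = (w * stats.norm.cdf((self.threshold - m1) / s1)
               + (1 - w) * stats.norm.cdf((self.threshold - m2) / s2))
        return [mean - self.mean,
                second - (self.sd**2 + self.mean**2),
                cdf - self.p]

    def _solve(self):
        guesses = [
            (self.threshold - self.s1, None, self.sd),
            (self.mean - self.sd, None, self.sd),
            (self.threshold - 2 * self.s1, None, 0.8 * self.sd),
        ]
        best = None
        for m1_0, _, s2_0 in guesses:
            m2_0 = (self.mean - self.w * m1_0) / (1 - self.w)
            sol = optimize.least_squares(
                self._equations, x0=[m1_0, m2_0, s2_0],
                bounds=([-np.inf, -np.inf, 1e-6 * self.sd],
                        [np.inf, np.inf, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.cost < 1e-16:
                break
        if best is None or best.cost > 1e-12:
            raise InvalidSpecError(
                f"cannot match mean={self.mean}, sd={self.sd} and "
                f"P(X<{self.threshold})={self.p} with the mixture marginal "
                "(requested prevalence incompatible with the moments)"
            )
        self.m1, self.m2, self.s2 = (float(v) for v in best.x)

    def cdf(self, x):
        return (self.w * stats.norm.cdf((x - self.m1) / self.s1)
                + (1 - self.w) * stats.norm.cdf((x - self.m2) / self.s2))

    def _build_quantile_table(self):
        lo = min(self.m1 - 8 * self.s1, self.m2 - 8 * self.s2)
        hi = max(self.m1 + 8 * self.s1, self.m2 + 8 * self.s2)
        grid = np.union1d(np.linspace(lo, hi, 20001), [self.threshold])
        cdf = self.cdf(grid)
        keep = np.concatenate(([True], np.diff(cdf) > 0))
        self._xgrid, self._cgrid = grid[keep], cdf[keep]

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map standard-normal draws through the quantile function."""
        u = stats.norm.cdf(z)
        return np.interp(u, self._cgrid, self._xgrid)

    def _attenuation(self) -> float:
        """Pearson attenuation lambda = corr(Z, T(Z)) under the copula."""
        nodes, weights = np.polynomial.hermite_e.hermegauss(201)
        w = weights / weights.sum()
        t = self.transform(nodes)
        mu = float(w @ t)
        var = float(w @ (t - mu) ** 2)
        cov = float(w @ (nodes * (t - mu)))
        return cov / np.sqrt(var)


def _latent_rho_for_pair(m1: _MixtureMarginal, m2: _MixtureMarginal,
                         target: float) -> float:
    """Latent correlation giving Pearson ``target`` between two transformed columns."""
    if target == 0.0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    w = weights / weights.sum()
    t1 = m1.transform(nodes)
    mu1 = float(w @ t1)
    sd1 = float(np.sqrt(w @ (t1 - mu1) ** 2))

    def pearson_at(rho: float) -> float:
        z2 = rho * nodes[:, None] + np.sqrt(1 - rho**2) * nodes[None, :]
        t2 = m2.transform(z2)
        mu2 = float((w[:, None] * w[None, :] * t2).sum())
        e12 = float((w[:, None] * (t1[:, None] - mu1) * (w[None, :] * (t2 - mu2))).sum())
        v2 = float((w[:, None] * w[None, :] * (t2 - mu2) ** 2).sum())
        return e12 / (sd1 * np.sqrt(v2))

    lo, hi = (0.0, 0.999) if target > 0 else (-0.999, 0.0)
    f_lo, f_hi = pearson_at(lo) - target, pearson_at(hi) - target
    if f_lo * f_hi > 0:  # unattainable; use the closest endpoint
        return hi if target > 0 else lo
    return float(optimize.brentq(lambda r: pearson_at(r) - target, lo, hi,
                                 xtol=1e-6))


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Specification of a synthetic screening cohort.

    ``means``/``sds`` override reference values per parameter;
    ``correlations``, keyed by parameter pairs, *replaces* the reference
    correlation targets when given (unspecified pairs default to 0 before
    the positive-semi-definite repair).
    """

    n_patients: int = reference.COHORT_N
    seed: int = 0
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    correlations: dict[tuple[str, str], float] | None = None
    sasn_prevalence: float = reference.SASN_PREVALENCE
    rsav_prevalence: float = reference.RSAV_PREVALENCE
    female_fraction: float = reference.FEMALE_FRACTION

    def validate(self) -> None:
        if self.n_patients < 2:
            raise InvalidSpecError("n_patients must be >= 2")
        for name, (mean, sd) in self.stats().items():
            if sd <= 0:
                raise InvalidSpecError(f"SD for {name!r} must be > 0, got {sd}")
        for frac, what in ((self.sasn_prevalence, "sasn_prevalence"),
                           (self.rsav_prevalence, "rsav_prevalence"),
                           (self.female_fraction, "female_fraction")):
            if not 0 < frac < 1:
                raise InvalidSpecError(f"{what} must be in (0, 1), got {frac}")
        for pair, r in self.correlation_targets().items():
            if not -1.0 <= r <= 1.0:
                raise InvalidSpecError(f"correlation {pair} = {r} outside [-1, 1]")

    def stats(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in DRAWN_COLUMNS:
            mean, sd = reference.PARAMETER_STATS[name]
            out[name] = (self.means.get(name, mean), self.sds.get(name, sd))
        return out

    def correlation_targets(self) -> dict[tuple[str, str], float]:
        if self.correlations is not None:
            out = {}
            for (a, b), r in self.correlations.items():
                if a not in DRAWN_COLUMNS or b not in DRAWN_COLUMNS:
                    raise InvalidSpecError(
                        f"correlation target references non-drawn column: ({a}, {b})"
                    )
                out[tuple(sorted((a, b)))] = float(r)
            return out
        out = {}
        for name, r in reference.AMIN_CORRELATIONS.items():
            if name in DRAWN_COLUMNS:
                out[tuple(sorted(("A_min", name)))] = r
        for name, r in reference.VPAS_CORRELATIONS.items():
            if name in DRAWN_COLUMNS:
                out[tuple(sorted(("V_PAS", name)))] = r
        return out


def _assemble_target_matrix(spec: CohortSpec) -> np.ndarray:
    k = len(DRAWN_COLUMNS)
    idx = {c: i for i, c in enumerate(DRAWN_COLUMNS)}
    r = np.eye(k)
    for (a, b), rho in spec.correlation_targets().items():
        if a == b:
            continue
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
    return r


def generate_tabular_cohort(spec: CohortSpec | None = None):
    """Generate a synthetic cohort table.

    Returns a :class:`pandas.DataFrame` with one row per patient and all 38
    screening parameters plus age, gender ('f'/'m'), BH, BW and BMI.
    Deterministic under a fixed seed. ``df.attrs`` records the effective
    (PSD-repaired) correlation targets and the latent matrix actually used.
    """
    import pandas as pd

    spec = spec or CohortSpec()
    spec.validate()
    all_stats = spec.stats()

    marginals: dict[str, _NormalMarginal | _MixtureMarginal] = {}
    for name, (mean, sd) in all_stats.items():
        if name == "A_min":
            marginals[name] = _MixtureMarginal(
                mean, sd, reference.SASN_AMIN_CUT, spec.sasn_prevalence)
        elif name == "V_PAS":
            marginals[name] = _MixtureMarginal(
                mean, sd, reference.RSAV_VPAS_CUT, spec.rsav_prevalence)
        else:
            marginals[name] = _NormalMarginal(mean, sd)

    r_target = nearest_psd(_assemble_target_matrix(spec))

    # latent correlation: correct Pearson attenuation from the marginal maps
    idx = {c: i for i, c in enumerate(DRAWN_COLUMNS)}
    r_lat = r_target.copy()
    transformed = [c for c in DRAWN_COLUMNS
                   if isinstance(marginals[c], _MixtureMarginal)]
    for c in transformed:
        i = idx[c]
        lam = marginals[c].lam
        r_lat[i, :] = r_lat[i, :] / lam
        r_lat[:, i] = r_lat[:, i] / lam
        r_lat[i, i] = 1.0
    for a_i in range(len(transformed)):
        for b_i in range(a_i + 1, len(transformed)):
            a, b = transformed[a_i], transformed[b_i]
            rho = _latent_rho_for_pair(marginals[a], marginals[b],
                                       r_target[idx[a], idx[b]])
            r_lat[idx[a], idx[b]] = r_lat[idx[b], idx[a]] = rho
    r_lat = np.clip(r_lat, -0.999, 0.999)
    np.fill_diagonal(r_lat, 1.0)
    r_lat = nearest_psd(r_lat)

    chol = np.linalg.cholesky(r_lat + 1e-10 * np.eye(len(DRAWN_COLUMNS)))
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_patients, len(DRAWN_COLUMNS)
    z = rng.standard_normal((n, k)) @ chol.T
    for _ in range(100):  # redraw unphysiological tails (> 5 SD)
        bad = (np.abs(z) > 5.0).any(axis=1)
        if not bad.any():
            break
        z[bad] = rng.standard_normal((int(bad.sum()), k)) @ chol.T

    data = {c: marginals[c].transform(z[:, idx[c]]) for c in DRAWN_COLUMNS}

    z_gender = rng.standard_normal(n)
    data["gender"] = np.where(z_gender < stats.norm.ppf(spec.female_fraction),
                              "f", "m")

    # derived columns: keep the record-level identities exact
    data["ANB"] = data["SNA"] - data["SNB"]
    data["Sum"] = data["NSAr"] + data["SArGo"] + data["ArGoMe"]
    data["S-Go/N-Me"] = data["S-Go"] / data["N-Me"]
    data["Ans-Me/N-Ans"] = data["Ans-Me"] / data["N-Ans"]
    data["BMI"] = data["BW"] / (data["BH"] / 100.0) ** 2

    df = pd.DataFrame({c: data[c] for c in COHORT_COLUMNS})
    df.attrs["seed"] = spec.seed
    df.attrs["effective_correlations"] = pd.DataFrame(
        r_target, index=list(DRAWN_COLUMNS), columns=list(DRAWN_COLUMNS))
    df.attrs["latent_correlations"] = pd.DataFrame(
        r_lat, index=list(DRAWN_COLUMNS), columns=list(DRAWN_COLUMNS))
    return df
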