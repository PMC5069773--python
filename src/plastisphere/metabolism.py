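"""Light/dark bottle oxygen metabolism and chlorophyll normalization.

Community metabolic rates on plastic particles and in surrounding
seawater are estimated from Winkler-style bottle incubations:

* NCP (net community production) — oxygen gained in the light bottles
  relative to the time-zero bottles,
* R (community respiration) — oxygen lost in the dark bottles relative
  to time zero,
* GPP (gross primary production) — NCP + R, by construction.

Bottles amended with plastic pieces displace some seawater, so oxygen
concentrations are first converted to total moles over the effective
water volume.  Per-particle rates are background-corrected by
subtracting the unamended seawater bottle rates.

Chlorophyll a on plastic is normalized to particle surface area
(mg/m^2) and compared with the volumetric water-column concentration
(mg/m^3) via a seawater-equivalence volume: the millilitres of seawater
holding as much Chl a as one particle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .stats import bh_adjust, dunn_test, mannwhitney_u

__all__ = [
    "RateEstimate",
    "BottleRateEstimator",
    "displacement_adjust",
    "bottle_rates",
    "background_subtract",
    "chl_per_area",
    "sphere_surface_area",
    "seawater_equiv_volume",
    "size_class_test",
    "two_group_rate_test",
    "read_bottle_table",
    "read_chl_table",
]

HOURS_PER_DAY = 24.0


@dataclass
class RateEstimate:
    """NCP, R and GPP with standard errors; gpp == ncp + r always."""

    ncp: float
    r: float
    se_ncp: float
    se_r: float
    n_light: int
    n_dark: int
    n_t0: int
    units: str = "umol_O2_per_L_per_day"

    @property
    def gpp(self) -> float:
        return self.ncp + self.r

    @property
    def se_gpp(self) -> float:
        # NCP and R share the t0 mean; conservative independent propagation
        return float(np.hypot(self.se_ncp, self.se_r))

    def to_dict(self) -> dict:
        return {
            "ncp": self.ncp,
            "r": self.r,
            "gpp": self.gpp,
            "se_ncp": self.se_ncp,
            "se_r": self.se_r,
            "se_gpp": self.se_gpp,
            "n_light": self.n_light,
            "n_dark": self.n_dark,
            "n_t0": self.n_t0,
            "units": self.units,
        }


def displacement_adjust(o2_conc, bottle_volume_L, particle_volume_L):
    """Total O2 (umol) in a bottle, over the water volume left by the particle.

    ``o2_conc`` is umol/L measured on the water; the particle displaces
    ``particle_volume_L`` of the bottle, so moles = conc x (bottle - particle).
    With no particle this is the identity conversion conc x bottle volume.
    """
    o2 = np.asarray(o2_conc, dtype=float)
    bv = np.asarray(bottle_volume_L, dtype=float)
    pv = np.asarray(particle_volume_L, dtype=float)
    if np.any(pv < 0) or np.any(pv >= bv):
        raise ValueError("particle_volume must satisfy 0 <= particle_volume < bottle_volume")
    return o2 * (bv - pv)


def bottle_rates(light, dark, t0, duration_h: float = 24.0,
                 units: str = "umol_O2_per_L_per_day") -> RateEstimate:
    """Two-point NCP/R/GPP from replicate light, dark and time-zero bottles.

    Inputs are per-bottle oxygen values in a common unit (concentration,
    or displacement-adjusted moles).  Rates are scaled to per-day:

        NCP = (mean(light) - mean(t0)) * 24 / duration
        R   = (mean(t0) - mean(dark)) * 24 / duration
        GPP = NCP + R

    Standard errors are propagated from within-treatment variance.
    """
    light = np.asarray(light, dtype=float)
    dark = np.asarray(dark, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    for name, arr in (("light", light), ("dark", dark), ("t0", t0)):
        if arr.size < 1:
            raise ValueError(f"missing treatment group: {name}")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    scale = HOURS_PER_DAY / duration_h

    def sem2(x):
        return x.var(ddof=1) / x.size if x.size > 1 else 0.0

    ncp = (light.mean() - t0.mean()) * scale
    r = (t0.mean() - dark.mean()) * scale
    return RateEstimate(
        ncp=float(ncp),
        r=float(r),
        se_ncp=float(np.sqrt(sem2(light) + sem2(t0)) * scale),
        se_r=float(np.sqrt(sem2(t0) + sem2(dark)) * scale),
        n_light=light.size,
        n_dark=dark.size,
        n_t0=t0.size,
        units=units,
    )


def background_subtract(amended: RateEstimate, control: RateEstimate,
                        n_particles: int = 1) -> RateEstimate:
    """Per-particle rates: amended bottle rates minus unamended seawater rates.

    One particle per amended bottle is the standard incubation design, so
    ``n_particles`` defaults to 1.  The GPP = NCP + R identity is preserved
    because the subtraction is component-wise and GPP is derived.
    """
    if amended.units != control.units:
        raise ValueError(f"unit mismatch: {amended.units} vs {control.units}")
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    return replace(
        amended,
        ncp=(amended.ncp - control.ncp) / n_particles,
        r=(amended.r - control.r) / n_particles,
        se_ncp=float(np.hypot(amended.se_ncp, control.se_ncp)) / n_particles,
        se_r=float(np.hypot(amended.se_r, control.se_r)) / n_particles,
        units=amended.units + "_per_particle",
    )


class BottleRateEstimator(BaseEstimator):
    """Estimator computing displacement-adjusted rates per incubation experiment.

    ``fit`` takes a tidy bottle table with columns ``experiment_id``,
    ``treatment`` ({light, dark, t0}), ``o2_umol_per_L``,
    ``bottle_volume_L``, ``particle_volume_L``, ``duration_h`` and stores
    one :class:`RateEstimate` per experiment in ``rates_`` (total-moles
    units, umol O2 per bottle per day).
    """

    def __init__(self, background_experiment: str | None = None):
        self.background_experiment = background_experiment

    def fit(self, X: pd.DataFrame, y=None):
        required = {"experiment_id", "treatment", "o2_umol_per_L",
                    "bottle_volume_L", "particle_volume_L"}
        missing = required - set(X.columns)
        if missing:
            raise ValueError(f"bottle table missing columns: {sorted(missing)}")
        rates: dict[str, RateEstimate] = {}
        for exp_id, sub in X.groupby("experiment_id"):
            adj = displacement_adjust(
                sub["o2_umol_per_L"], sub["bottle_volume_L"], sub["particle_volume_L"]
            )
            groups = {t: adj[sub["treatment"] == t] for t in ("light", "dark", "t0")}
            empty = [t for t, v in groups.items() if len(v) == 0]
            if empty:
                raise ValueError(f"experiment {exp_id!r} missing treatments: {empty}")
            duration = float(sub["duration_h"].iloc[0]) if "duration_h" in sub else 24.0
            rates[exp_id] = bottle_rates(
                groups["light"], groups["dark"], groups["t0"],
                duration_h=duration, units="umol_O2_per_bottle_per_day",
            )
        self.rates_ = rates
        if self.background_experiment is not None:
            control = rates[self.background_experiment]
            self.particle_rates_ = {
                k: background_subtract(v, control)
                for k, v in rates.items()
                if k != self.background_experiment
            }
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for exp, est in self.rates_.items():
            rows.append({"experiment_id": exp, **est.to_dict()})
        if getattr(self, "particle_rates_", None):
            for exp, est in self.particle_rates_.items():
                rows.append({"experiment_id": f"{exp} (per particle)", **est.to_dict()})
        return pd.DataFrame(rows)


def sphere_surface_area(diameter_mm) -> float:
    """Surface area (m^2) of a sphere of the given diameter in mm: pi d^2."""
    d = np.asarray(diameter_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    return np.pi * (d / 1000.0) ** 2


def chl_per_area(chl_mass_mg, surface_area_m2):
    """Areal chlorophyll density mg/m^2 on a particle."""
    area = np.asarray(surface_area_m2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("surface_area must be positive")
    return np.asarray(chl_mass_mg, dtype=float) / area


def seawater_equiv_volume(chl_areal_mg_m2, surface_area_m2, chl_water_mg_m3):
    """Millilitres of seawater holding as much Chl a as one particle.

    ``chl_areal x area / chl_water`` gives m^3, converted to mL (x 1e6).
    Linear in the particle's areal chlorophyll and inversely proportional
    to the water-column concentration.
    """
    chl_w = np.asarray(chl_water_mg_m3, dtype=float)
    if np.any(chl_w <= 0):
        raise ValueError("water-column chlorophyll must be positive")
    areal = np.asarray(chl_areal_mg_m2, dtype=float)
    area = np.asarray(surface_area_m2, dtype=float)
    return areal * area / chl_w * 1e6


def size_class_test(chl_by_class: dict, alpha: float = 0.05):
    """Kruskal-Wallis omnibus across size classes plus Dunn post-hoc.

    Returns ``(omnibus_p, pairwise_df)``; the pairwise frame carries BH
    adjusted p-values and a ``significant`` flag at ``alpha``.  All-tied
    degenerate data is reported as non-significant (p = 1) rather than
    an error.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in chl_by_class.items()}
    if len(groups) < 2:
        raise ValueError("need at least two size classes")
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("need at least two values per size class")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        import warnings

        warnings.warn("all observations tied; omnibus test degenerate", stacklevel=2)
        pairwise = dunn_test(groups)
        pairwise["significant"] = False
        return 1.0, pairwise
    omnibus_p = float(stats.kruskal(*groups.values()).pvalue)
    pairwise = dunn_test(groups)
    pairwise["significant"] = pairwise["p_adjusted"] < alpha
    return omnibus_p, pairwise


def two_group_rate_test(a, b, method: str = "mann_whitney") -> float:
    """Two-sided p-value comparing two groups of rates.

    ``method='mann_whitney'`` uses the exact rank test for small
    tie-free samples and the tie-corrected normal approximation
    otherwise; ``method='anova'`` is a one-way ANOVA on two groups
    (equivalent to a pooled-variance t-test).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if method == "mann_whitney":
        return mannwhitney_u(a, b)
    if method == "anova":
        if np.all(np.concatenate([a, b]) == a[0]):
            return 1.0
        return float(stats.f_oneway(a, b).pvalue)
    raise ValueError(f"unknown method: {method!r}")


def read_bottle_table(path) -> pd.DataFrame:
    """Read a bottle TSV (experiment_id, station, treatment, size_class,
    o2_umol_per_L, bottle_volume_L, particle_volume_L, duration_h)."""
    df = pd.read_csv(path, sep="\t")
    bad = set(df["treatment"].unique()) - {"light", "dark", "t0"}
    if bad:
        raise ValueError(f"unknown treatments: {sorted(bad)}")
    return df


def read_chl_table(path) -> pd.DataFrame:
    """Read a chlorophyll TSV (station, substrate, size_class, chl_value,
    chl_units, surface_area_m2)."""
    return pd.read_csv(path, sep="\t")
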