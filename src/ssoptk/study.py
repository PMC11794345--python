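"""Synthetic lobe-level study tables for the hemi-hepatic ischemia design.

The in-vivo study design: two groups of six swine — total vascular inflow
occlusion (TVIO: left hepatic artery branches + left portal vein clamped)
and hepatic artery occlusion (HAO: arteries only) — measured on three liver
lobes (LL, LM, RM) at baseline (T0), 30 min of ischemia (T1) and 30 min of
reperfusion (T2).  Three variables per (animal, lobe, timepoint): the
structured-light StO2 (%), capillary lactate (mmol/L) and a contact
oximeter reference StO2 (%).

``PRINTED_CELL_STATS`` holds the reported group means/SDs of that design;
reperfusion cells reuse baseline values (StO2 returned promptly to baseline
after declamping).  ``simulate_study`` draws per-animal values around those
cell statistics, with lactate (and the reference oximeter) linearly coupled
to the same animal's StO2 deviation so the pooled Pearson correlations can
be calibrated to a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("TVIO", "HAO")
LOBES = ("LL", "LM", "RM")
TIMEPOINTS = ("T0", "T1", "T2")
VARIABLES = ("sto2", "lactate", "ref_sto2")


def _expand(t0_t1: dict) -> dict:
    """Fill T2 with the T0 cell (reperfusion returns to baseline)."""
    out = {}
    for (g, lobe), ((m0, s0), (m1, s1)) in t0_t1.items():
        out[(g, lobe, "T0")] = (m0, s0)
        out[(g, lobe, "T1")] = (m1, s1)
        out[(g, lobe, "T2")] = (m0, s0)
    return out


#: Reported group mean ± SD per (group, lobe, timepoint).
PRINTED_CELL_STATS: dict[str, dict[tuple[str, str, str], tuple[float, float]]] = {
    "sto2": _expand({
        ("TVIO", "LL"): ((46.0, 5.1), (16.2, 5.1)),
        ("TVIO", "LM"): ((42.7, 5.9), (6.4, 4.0)),
        ("TVIO", "RM"): ((48.0, 7.7), (43.2, 5.3)),
        ("HAO", "LL"): ((32.7, 6.4), (19.1, 5.4)),
        ("HAO", "LM"): ((35.3, 8.2), (15.5, 5.8)),
        ("HAO", "RM"): ((42.5, 5.7), (38.9, 5.4)),
    }),
    "lactate": _expand({
        ("TVIO", "LL"): ((1.3, 0.4), (8.5, 2.4)),
        ("TVIO", "LM"): ((1.3, 0.4), (8.2, 2.1)),
        ("TVIO", "RM"): ((1.1, 0.4), (2.2, 2.4)),
        ("HAO", "LL"): ((2.4, 0.9), (2.6, 1.1)),
        ("HAO", "LM"): ((2.5, 1.3), (2.5, 1.3)),
        ("HAO", "RM"): ((2.9, 1.0), (2.6, 0.8)),
    }),
    "ref_sto2": _expand({
        ("TVIO", "LL"): ((49.8, 1.6), (26.8, 2.2)),
        ("TVIO", "LM"): ((49.8, 2.4), (28.7, 1.9)),
        ("TVIO", "RM"): ((48.0, 3.0), (50.7, 2.2)),
        ("HAO", "LL"): ((50.3, 1.9), (38.3, 2.3)),
        ("HAO", "LM"): ((51.7, 1.7), (38.8, 1.8)),
        ("HAO", "RM"): ((50.2, 1.7), (52.5, 1.2)),
    }),
}

#: Default within-cell lactate coupling, mmol/L per StO2 percentage point.
#: Calibrated once (see ``calibrate_coupling``) so that the pooled Pearson
#: r(StO2, lactate) over both groups at n = 6 averages approximately -0.76.
DEFAULT_LACTATE_COUPLING = -0.281

#: Default within-cell reference-oximeter coupling (pp per pp), calibrated
#: toward a pooled r(StO2, ref StO2) of approximately +0.82.
DEFAULT_REF_COUPLING = 0.281


@dataclass
class StudySpec:
    """Design and noise parameters of one simulated study."""

    n_animals_per_group: int = 6
    groups: tuple[str, ...] = GROUPS
    lobes: tuple[str, ...] = LOBES
    timepoints: tuple[str, ...] = TIMEPOINTS
    cell_stats: Mapping[str, Mapping[tuple[str, str, str], tuple[float, float]]] = field(
        default_factory=lambda: PRINTED_CELL_STATS
    )
    lactate_coupling: float = DEFAULT_LACTATE_COUPLING
    ref_coupling: float = DEFAULT_REF_COUPLING
    noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValueError("need at least one animal per group")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        for var in VARIABLES:
            table = self.cell_stats[var]
            for g in self.groups:
                for lobe in self.lobes:
                    for tp in self.timepoints:
                        if (g, lobe, tp) not in table:
                            raise ValueError(f"missing cell stats for {var} {(g, lobe, tp)}")
                        if table[(g, lobe, tp)][1] <= 0:
                            raise ValueError(f"non-positive sd for {var} {(g, lobe, tp)}")

    def with_zero_noise(self) -> "StudySpec":
        return replace(self, noise_scale=0.0)


def _coupled_draw(
    rng: np.random.Generator,
    primary_dev: float,
    sd_primary: float,
    mean: float,
    sd: float,
    coupling: float,
) -> float:
    """Draw a variable with total SD ``sd`` whose deviation contains
    ``coupling * primary_dev`` plus independent residual noise.

    The coupling is capped per cell so the implied correlated component
    never exceeds the cell's own SD (residual variance stays >= 0).
    """
    if sd <= 0:
        return mean + 0.0
    cap = sd / max(sd_primary, 1e-12)
    k = np.sign(coupling) * min(abs(coupling), cap)
    resid_sd = np.sqrt(max(sd**2 - (k * sd_primary) ** 2, 0.0))
    return mean + k * primary_dev + rng.normal(0.0, resid_sd)


def simulate_study(spec: StudySpec) -> pd.DataFrame:
    """Draw one study table; deterministic for a fixed ``spec.seed``.

    StO2 is drawn per cell; lactate and reference StO2 inherit a linear
    share of the same animal's StO2 deviation (negative for lactate,
    positive for the reference oximeter) with residual noise sized so each
    cell's total SD matches its specified SD.  With ``noise_scale = 0``
    every value equals its cell mean exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.groups:
        for a in range(spec.n_animals_per_group):
            animal = f"{g}-{a + 1:02d}"
            for lobe in spec.lobes:
                for tp in spec.timepoints:
                    m_s, sd_s = spec.cell_stats["sto2"][(g, lobe, tp)]
                    m_l, sd_l = spec.cell_stats["lactate"][(g, lobe, tp)]
                    m_r, sd_r = spec.cell_stats["ref_sto2"][(g, lobe, tp)]
                    sd_s_eff = sd_s * spec.noise_scale
                    sto2 = m_s + rng.normal(0.0, sd_s_eff) if sd_s_eff > 0 else m_s
                    dev = sto2 - m_s
                    lact = _coupled_draw(
                        rng, dev, sd_s_eff, m_l, sd_l * spec.noise_scale,
                        spec.lactate_coupling,
                    )
                    ref = _coupled_draw(
                        rng, dev, sd_s_eff, m_r, sd_r * spec.noise_scale,
                        spec.ref_coupling,
                    )
                    rows.append(
                        {
                            "animal_id": animal,
                            "group": g,
                            "lobe": lobe,
                            "timepoint": tp,
                            "sto2": sto2,
                            "lactate": lact,
                            "ref_sto2": ref,
                        }
                    )
    return pd.DataFrame(rows)


def mean_pooled_correlation(
    spec: StudySpec,
    var_x: str = "sto2",
    var_y: str = "lactate",
    n_reps: int = 200,
    seed: int = 1234,
) -> float:
    """Monte Carlo mean of the pooled sample Pearson r over replicates."""
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rs = []
    for s in seeds:
        tab = simulate_study(replace(spec, seed=int(s)))
        r, _ = stats.pearsonr(tab[var_x], tab[var_y])
        rs.append(r)
    return float(np.mean(rs))


def calibrate_coupling(
    spec: StudySpec | None = None,
    target_r: float = -0.76,
    var_y: str = "lactate",
    bounds: tuple[float, float] = (-1.5, 0.0),
    n_reps: int = 200,
    seed: int = 1234,
    tol: float = 0.005,
) -> float:
    """Find the within-cell coupling giving a target pooled correlation.

    Bisection on the coupling coefficient, using common random numbers so
    the Monte Carlo objective is monotone and smooth.  If the target lies
    outside the achievable range the nearest bound is returned.
    """
    spec = spec or StudySpec()
    attr = "lactate_coupling" if var_y == "lactate" else "ref_coupling"

    def mean_r(k: float) -> float:
        return mean_pooled_correlation(
            replace(spec, **{attr: k}), "sto2", var_y, n_reps=n_reps, seed=seed
        )

    lo, hi = bounds
    r_lo, r_hi = mean_r(lo), mean_r(hi)
    if not (min(r_lo, r_hi) - tol <= target_r <= max(r_lo, r_hi) + tol):
        return lo if abs(r_lo - target_r) < abs(r_hi - target_r) else hi
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        r_mid = mean_r(mid)
        if abs(r_mid - target_r) < tol:
            return mid
        # r is monotone in k along the bracket
        if (r_mid - target_r) * (r_lo - target_r) > 0:
            lo, r_lo = mid, r_mid
        else:
            hi, r_hi = mid, r_mid
    return 0.5 * (lo + hi)
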