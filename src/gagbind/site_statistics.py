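"""Binding-probability tables and energy-per-contact regression.

Per-site binding probabilities are simple binomial proportions over the
full trajectory ensemble, reported with a one-standard-error binomial
confidence half-width 100 sqrt(p(1-p)/n) — the convention that reproduces
published binding tables of this kind.  The interaction-energy score is
the screened-Coulomb pair energy, and the contacts-vs-energy relationship
is summarized by an ordinary least-squares slope (kcal/mol per contact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import electrostatics


@dataclass
class EnergyRegression:
    slope: float          # kcal/mol per contact
    slope_se: float
    intercept: float
    n_points: int


def binding_percent(n_bound: int, n_total: int) -> float:
    """Bound percentage 100 * n_bound / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_bound <= n_total:
        raise ValueError("need 0 <= n_bound <= n_total")
    return 100.0 * n_bound / n_total


def binomial_ci_halfwidth(n_bound: int, n_total: int) -> float:
    """One-standard-error binomial half-width, in percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_bound <= n_total:
        raise ValueError("need 0 <= n_bound <= n_total")
    p = n_bound / n_total
    return 100.0 * math.sqrt(p * (1.0 - p) / n_total)


def _round_sig(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_percent_pair(percent: float, ci: float) -> tuple[str, str]:
    """Table-style rounding: CI to 1 significant figure, percent to the
    same decimal place (e.g. 24.2 ± 0.1, 5.22 ± 0.05, 0.058 ± 0.005)."""
    if ci == 0:
        return f"{percent:.1f}", "0"
    ci_r = _round_sig(ci, 1)
    decimals = max(0, -int(math.floor(math.log10(ci_r))))
    return f"{percent:.{decimals}f}", f"{ci_r:.{decimals}f}"


def site_table(outcomes, site_groups=None,
               sites=None) -> pd.DataFrame:
    """Per-site binding table from a BD outcome list.

    ``site_groups`` maps a row label to an iterable of residue numbers to
    pool (e.g. composite K317-K321 sites); ungrouped sites get one row
    each.  The denominator is the full trajectory count, so escaped and
    step-capped trajectories lower every percentage.
    """
    if not outcomes:
        raise ValueError("outcome list is empty")
    n_total = len(outcomes)
    reacted = {}
    for out in outcomes:
        if out.status == "reacted":
            reacted[out.site] = reacted.get(out.site, 0) + 1
    if sites is None:
        sites = sorted(reacted)
    site_groups = dict(site_groups or {})
    grouped = {r for members in site_groups.values() for r in members}
    rows = []
    for label, members in site_groups.items():
        n_b = sum(reacted.get(r, 0) for r in members)
        rows.append((str(label), n_b))
    for r in sites:
        if r not in grouped:
            rows.append((str(r), reacted.get(r, 0)))
    table = []
    for label, n_b in rows:
        pct = binding_percent(n_b, n_total)
        ci = binomial_ci_halfwidth(n_b, n_total)
        table.append({"site": label, "n_bound": n_b, "n_total": n_total,
                      "percent": pct, "ci_halfwidth": ci})
    return pd.DataFrame(table)


def interaction_energy(fibril, glycan, pose, solvent,
                       include_wall: bool = True) -> float:
    """Screened-Coulomb (+ soft-wall) energy of a posed glycan, kcal/mol."""
    world = pose.apply(glycan.charge_positions)
    return electrostatics.interaction_energy(fibril, world,
                                             glycan.charge_values, solvent,
                                             include_wall=include_wall)


def energy_per_contact(contact_counts, energies) -> EnergyRegression:
    """OLS slope of interaction energy on salt-bridge contact count."""
    x = np.asarray(contact_counts, dtype=float)
    y = np.asarray(energies, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired (count, energy) points")
    if len(np.unique(x)) < 2:
        raise ValueError("all contact counts identical: slope undefined")
    res = stats.linregress(x, y)
    se = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return EnergyRegression(slope=float(res.slope), slope_se=se,
                            intercept=float(res.intercept), n_points=len(x))
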