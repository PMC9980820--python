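"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the arrival-time
distribution comes from an exact dynamic program over (moves made, period)
states, and the ANOVA cross-checks go through scipy / pingouin.
"""

import numpy as np


def arrival_time_pmf(moves_needed: int, p_baseline: float, omega: float,
                     t_max: int) -> np.ndarray:
    """Exact P(arrival period = t) for a single traveller, t = 0..t_max.

    The traveller needs ``moves_needed`` outward moves; in period t it moves
    with probability min(1, p_baseline + t*omega).  The probability update
    happens at the start of each period, so period t uses p_baseline +
    t*omega.  (A lone non-social individual is never behind the refuge and
    never reaches the site before its last move, so no other branch of the
    decision flow can fire.)
    """
    q = np.zeros(moves_needed)  # q[m] = P(m moves made, not yet arrived)
    q[0] = 1.0
    pmf = np.zeros(t_max + 1)
    for t in range(1, t_max + 1):
        pi = min(1.0, p_baseline + t * omega)
        pmf[t] = q[moves_needed - 1] * pi
        q[1:] = q[1:] * (1 - pi) + q[:-1] * pi
        q[0] = q[0] * (1 - pi)
    return pmf


def chi_square_gof(observed_times: np.ndarray, pmf: np.ndarray,
                   min_expected: float = 5.0):
    """Chi-square goodness of fit of sampled arrival times against a pmf.

    Adjacent periods are pooled until every bin's expected count reaches
    ``min_expected``; the trailing tail (including any probability beyond
    len(pmf)-1) forms the last bin.  Returns (statistic, dof, p_value).
    """
    from scipy import stats

    n = len(observed_times)
    counts = np.bincount(observed_times, minlength=len(pmf)).astype(float)
    if len(counts) > len(pmf):
        raise ValueError("observed arrival beyond the tabulated pmf support")
    expected = pmf * n
    obs_bins, exp_bins = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(counts, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_bins.append(o_acc)
            exp_bins.append(e_acc)
            o_acc = e_acc = 0.0
    # fold the remainder (and any truncated tail mass) into the last bin
    obs_bins[-1] += o_acc
    exp_bins[-1] += e_acc + n * (1.0 - pmf.sum())
    obs_bins = np.asarray(obs_bins)
    exp_bins = np.asarray(exp_bins)
    stat = ((obs_bins - exp_bins) ** 2 / exp_bins).sum()
    dof = len(obs_bins) - 1
    return stat, dof, stats.chi2.sf(stat, dof)


def mixed_anova_pingouin(table, response, level_col="value",
                         subject_col="replicate", id_col="identity"):
    """(parameter_F, individual_F, interaction_F) via pingouin.mixed_anova."""
    import pingouin as pg

    data = table.copy()
    data["_subject"] = (data[level_col].astype(str) + "|"
                        + data[subject_col].astype(str))
    aov = pg.mixed_anova(data=data, dv=response, within=id_col,
                         between=level_col, subject="_subject",
                         correction=False)
    aov = aov.set_index("Source")["F"]
    return (float(aov[level_col]), float(aov[id_col]),
            float(aov["Interaction"]))


def oneway_f_scipy(table, response, factor="value"):
    """One-way F via scipy.stats.f_oneway."""
    from scipy import stats

    groups = [g.to_numpy(dtype=float)
              for _, g in table.groupby(factor)[response]]
    return float(stats.f_oneway(*groups).statistic)
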