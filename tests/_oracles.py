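"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain
Python loops over years, rank sequences built by list concatenation,
and order statistics from an explicit sort.
"""

from __future__ import annotations


def rank_sequence(assistant_years, associate_years, reaches_full, T):
    """Rank label per career year, built by concatenation."""
    if assistant_years is None:
        return ["assistant"] * T
    seq = ["assistant"] * min(assistant_years, T)
    if associate_years is None:
        seq += ["associate"] * (T - len(seq))
        return seq
    seq += ["associate"] * min(associate_years, T - len(seq))
    filler = "full" if reaches_full else "associate"
    seq += [filler] * (T - len(seq))
    return seq


def brute_npv(salaries_by_year, effort, g, r, convention="beginning_of_year"):
    """Year-by-year discounted sum with scalar arithmetic."""
    total = 0.0
    for t, (s, e) in enumerate(zip(salaries_by_year, effort), start=1):
        cash = s * e * (1.0 + g) ** (t - 1)
        if convention == "beginning_of_year":
            total += cash / (1.0 + r) ** (t - 1)
        else:
            total += cash / (1.0 + r) ** t
    return total


def brute_scenario_npv(record, percentile, trajectory, plan, g, r, convention="beginning_of_year"):
    """Scenario NPV via rank_sequence + brute_npv (no package NPV code)."""
    ranks = rank_sequence(
        trajectory.assistant_years,
        trajectory.associate_years,
        trajectory.reaches_full,
        plan.career_years,
    )
    salaries = [record.salary(rk, percentile) for rk in ranks]
    return brute_npv(salaries, list(plan.effort), g, r, convention)


def brute_breakeven(record, percentile, deficit, reference, plan, g, r, max_extra=40):
    """Exhaustive scan over career extensions, recomputed from scratch."""
    T = plan.career_years
    ref = brute_scenario_npv(record, percentile, reference, plan, g, r)
    final_rank = rank_sequence(
        deficit.assistant_years, deficit.associate_years, deficit.reaches_full, T
    )[-1]
    s_final = record.salary(final_rank, percentile)
    for extra in range(0, max_extra + 1):
        ranks = rank_sequence(
            deficit.assistant_years, deficit.associate_years, deficit.reaches_full, T
        )
        salaries = [record.salary(rk, percentile) for rk in ranks]
        salaries += [s_final] * extra
        effort = list(plan.effort) + [1.0] * extra
        if brute_npv(salaries, effort, g, r) >= ref:
            return extra
    return None


def brute_median_quartiles(values):
    """Median by midpoint rule; quartiles by linear interpolation."""
    xs = sorted(values)
    n = len(xs)

    def at(q):
        pos = q * (n - 1)
        lo = int(pos)
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[hi] * frac

    return at(0.25), at(0.5), at(0.75)
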