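"""Report rendering: aligned text tables, tidy frames, and plots.

Display precision follows the study's conventions: currency to whole
dollars, rates to one decimal place, break-evens and per-visit values to
cents.  All rounding happens here — model outputs stay at full
precision.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .model import PeriodComparison
from .scenarios import ScenarioPoint


def _usd(x: float) -> str:
    return f"{x:,.0f}"


def _rate(x: float | None) -> str:
    return "-" if x is None else f"{100 * x:.1f}"


def format_comparison(cmp: PeriodComparison) -> str:
    """Render a pre/post comparison as an aligned text table mirroring
    the study's financial-metrics layout (operations block, then one
    block per costing framework, with a difference column)."""
    pre, post = cmp.pre_summary, cmp.post_summary
    rows: list[tuple[str, str, str, str]] = [
        ("ED operations", "", "", ""),
        ("  Patient volume, n", f"{pre.n_visits:,}", f"{post.n_visits:,}",
         f"{post.n_visits - pre.n_visits:,}"),
        ("  ED LOS (min), median", f"{pre.median_ed_los:,.0f}",
         f"{post.median_ed_los:,.0f}",
         f"{post.median_ed_los - pre.median_ed_los:,.0f}"),
        ("  Revenue per visit (US $)", f"{pre.revenue_per_visit:,.2f}",
         f"{post.revenue_per_visit:,.2f}",
         f"{post.revenue_per_visit - pre.revenue_per_visit:,.2f}"),
    ]
    for title, fw in (
        ("Hospital management level", cmp.hospital_management),
        ("Public policy level", cmp.public_policy),
    ):
        rows.append((title, "", "", ""))
        rows.append(("  Revenue (US $)", _usd(fw.pre.revenue), _usd(fw.post.revenue),
                     _usd(fw.revenue_diff)))
        rows.append(("  Costs (US $)", _usd(fw.pre.cost), _usd(fw.post.cost),
                     _usd(fw.cost_diff)))
        rows.append((
            "  Operating margin (US $), %",
            f"{_usd(fw.pre.margin)} ({_rate(fw.pre.margin_rate)})",
            f"{_usd(fw.post.margin)} ({_rate(fw.post.margin_rate)})",
            _usd(fw.margin_diff),
        ))
    header = ("Metric", "Preintervention", "Postintervention", "Difference")
    table = [header, *rows]
    widths = [max(len(r[i]) for r in table) for i in range(4)]
    lines = []
    for i, row in enumerate(table):
        lines.append("  ".join(
            cell.ljust(widths[0]) if j == 0 else cell.rjust(widths[j])
            for j, cell in enumerate(row)
        ).rstrip())
        if i == 0:
            lines.append("-" * (sum(widths) + 6))
    return "\n".join(lines)


def sweep_to_frame(points: Sequence[ScenarioPoint]) -> pd.DataFrame:
    """Tidy one-row-per-grid-point frame of a sensitivity sweep."""
    rows = []
    for p in points:
        rows.append({
            "e": p.e,
            "ed_los_min": p.ed_los,
            "volume": p.volume,
            "revenue": p.hospital_management.revenue,
            "hm_cost": p.hospital_management.cost,
            "hm_margin": p.hospital_management.margin,
            "policy_cost": p.public_policy.cost,
            "policy_margin": p.public_policy.margin,
            "hm_break_even_per_visit": p.break_even_hm().per_visit,
            "policy_break_even_per_visit": p.break_even_policy().per_visit,
        })
    return pd.DataFrame(rows)


def format_scenario_point(p: ScenarioPoint) -> str:
    be_hm, be_pp = p.break_even_hm(), p.break_even_policy()
    lines = [
        f"scenario: {p.kind}   e = {p.e:+.2%}",
        f"  projected volume: {p.volume:,.0f}   projected median ED LOS: {p.ed_los:,.1f} min",
        f"  hospital management: revenue {_usd(p.hospital_management.revenue)}, "
        f"cost {_usd(p.hospital_management.cost)}, "
        f"margin {_usd(p.hospital_management.margin)} "
        f"({_rate(p.hospital_management.margin_rate)}%)",
        f"  public policy:       revenue {_usd(p.public_policy.revenue)}, "
        f"cost {_usd(p.public_policy.cost)}, "
        f"margin {_usd(p.public_policy.margin)} "
        f"({_rate(p.public_policy.margin_rate)}%)",
        f"  break-even tool cost per visit: "
        f"HM {be_hm.per_visit:,.2f}  policy {be_pp.per_visit:,.2f}"
        + ("" if be_hm.sustainable else "  [no sustainable tool cost under HM]"),
    ]
    return "\n".join(lines)


def plot_sweep(points: Sequence[ScenarioPoint], path) -> None:
    """Two-panel margin/break-even plot over the efficiency grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = sweep_to_frame(points)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    x = 100 * frame["e"]
    ax1.plot(x, frame["hm_margin"] / 1e6, label="Hospital management")
    ax1.plot(x, frame["policy_margin"] / 1e6, label="Public policy")
    ax1.set_xlabel("Efficiency change e (%)")
    ax1.set_ylabel("Operating margin (US $ millions)")
    ax1.legend()
    ax2.plot(x, frame["hm_break_even_per_visit"], label="Hospital management")
    ax2.plot(x, frame["policy_break_even_per_visit"], label="Public policy")
    ax2.axhline(0, color="grey", lw=0.5)
    ax2.set_xlabel("Efficiency change e (%)")
    ax2.set_ylabel("Break-even tool cost per visit (US $)")
    ax2.legend()
    fig.suptitle(f"Sensitivity sweep — {points[0].kind}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
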