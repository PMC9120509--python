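"""Broad-sense heritability from replicate survivorship trials.

H^2 is the one-way-ANOVA mean-square ratio MS_between / (MS_between +
MS_within) with phenotype group as the factor — the share of replicate
survivorship variance attributable to parental phenotype.  It can be
computed either from the replicate table itself or reconstructed from
printed group summaries (mean, SE, n), and the two agree exactly when the
summaries come from the replicates.  The ratio is invariant to affine
rescaling of the response (percent vs proportion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AnovaSummary", "h2_from_replicates", "h2_from_summary"]


@dataclass
class AnovaSummary:
    """One-way ANOVA decomposition and the derived H^2."""

    groups: pd.DataFrame          # index: group; mean, sd, se, n
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    h2: float
    degenerate: bool = False      # zero between AND within variance

    def __repr__(self) -> str:  # compact, for notebooks/CLI
        return (f"AnovaSummary(H2={self.h2:.4f}, MSb={self.ms_between:.4g}, "
                f"MSw={self.ms_within:.4g}, k={len(self.groups)})")


def _anova(groups: dict[str, np.ndarray]) -> AnovaSummary:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for a one-way ANOVA")
    means, rows = {}, []
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        if len(v) < 2:
            raise ValueError(f"group '{g}' has fewer than 2 replicates")
        groups[g] = v
        means[g] = v.mean()
        rows.append({"group": g, "mean": v.mean(),
                     "sd": v.std(ddof=1), "se": v.std(ddof=1) / np.sqrt(len(v)),
                     "n": len(v)})
    all_v = np.concatenate(list(groups.values()))
    grand = all_v.mean()
    ss_b = float(sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values()))
    ss_w = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    df_b = len(groups) - 1
    df_w = len(all_v) - len(groups)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    degenerate = ms_b == 0 and ms_w == 0
    h2 = np.nan if degenerate else ms_b / (ms_b + ms_w)
    return AnovaSummary(
        groups=pd.DataFrame(rows).set_index("group"),
        ss_between=ss_b, ss_within=ss_w,
        ms_between=ms_b, ms_within=ms_w,
        h2=float(h2), degenerate=degenerate,
    )


def h2_from_replicates(
    table: pd.DataFrame,
    temperature: str | None = None,
    exclude_groups: tuple[str, ...] = ("cross",),
    group_col: str = "phenotype",
    value_col: str = "prop_surviving",
) -> AnovaSummary:
    """H^2 from a replicate survivorship table.

    `table` has one row per replicate with columns `group_col`,
    temperature, `value_col`.  The site-wide cross is excluded by default
    (it is not a pure phenotype group); pass `temperature` to restrict to
    one arm.
    """
    sub = table
    if temperature is not None:
        sub = sub[sub["temperature"] == temperature]
    sub = sub[~sub[group_col].isin(exclude_groups)]
    groups = {str(g): v[value_col].to_numpy() for g, v in sub.groupby(group_col)}
    return _anova(groups)


def h2_from_summary(means, ses, ns, names=None) -> AnovaSummary:
    """H^2 reconstructed from per-group (mean, SE, n) summaries.

    SD_g = SE_g * sqrt(n_g); SS_within = sum (n_g - 1) SD_g^2;
    SS_between = sum n_g (mean_g - grand)^2 with the grand mean weighted by
    n; H^2 = MS_between / (MS_between + MS_within) as above.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(ses) == len(ns)):
        raise ValueError("means, SEs and ns must have equal length")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if names is None:
        names = [f"group{i + 1}" for i in range(len(means))]
    sds = ses * np.sqrt(ns)
    grand = float((ns * means).sum() / ns.sum())
    ss_b = float((ns * (means - grand) ** 2).sum())
    ss_w = float(((ns - 1) * sds**2).sum())
    df_b = len(means) - 1
    df_w = int(ns.sum() - len(means))
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    degenerate = ms_b == 0 and ms_w == 0
    h2 = np.nan if degenerate else ms_b / (ms_b + ms_w)
    groups = pd.DataFrame(
        {"mean": means, "sd": sds, "se": ses, "n": ns},
        index=pd.Index(names, name="group"),
    )
    return AnovaSummary(groups=groups, ss_between=ss_b, ss_within=ss_w,
                        ms_between=ms_b, ms_within=ms_w, h2=float(h2),
                        degenerate=degenerate)
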