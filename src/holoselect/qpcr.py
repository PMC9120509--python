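"""qPCR symbiont quantification: replicate QC and proportion Durusdinium.

Colonies are assayed with genus-specific actin primers (Cladocopium "C",
Durusdinium "D") in technical duplicate on several branch replicates.
CT values convert to relative template copies assuming perfect doubling
(configurable efficiency), with optional per-assay fluorescence offsets
and per-genus actin copy numbers; the symbiont state of a branch is the
corrected fraction D / (C + D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QpcrCorrections",
    "qc_replicates",
    "proportion_durusdinium",
    "summarize_colony",
    "symbiont_profiles",
]

#: replicate QC outcomes
PASS, FAIL_SD, FAIL_SINGLE, ABSENT = "PASS", "FAIL_SD", "FAIL_SINGLE", "ABSENT"


@dataclass(frozen=True)
class QpcrCorrections:
    """Fluorescence offsets (cycles) and actin copy numbers per genus.

    Defaults are identity (no correction); published constants can be
    supplied without code change.  `efficiency` is the per-cycle
    amplification factor (2 = perfect doubling).
    """

    f_c: float = 0.0
    f_d: float = 0.0
    c_c: float = 1.0
    c_d: float = 1.0
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.c_c <= 0 or self.c_d <= 0:
            raise ValueError("actin copy numbers must be positive")
        if self.efficiency <= 1:
            raise ValueError("amplification efficiency must exceed 1")


def qc_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Flag technical-replicate groups of one assay on one sample.

    `records` has one row per technical replicate with columns identifying
    the group (every column except tech_rep/ct) and a `ct` column where NaN
    means no amplification.  Per group: FAIL_SD if the replicate CT
    standard deviation exceeds 1 cycle, FAIL_SINGLE if exactly one
    replicate amplified, ABSENT if none did (a legitimate zero for that
    genus, not a failure), PASS otherwise.  Returns one row per group with
    mean_ct, n_amplified and qc_flag.
    """
    keys = [c for c in records.columns if c not in ("tech_rep", "ct")]
    rows = []
    for key, sub in records.groupby(keys, sort=True, dropna=False):
        cts = sub["ct"].to_numpy(dtype=float)
        amp = cts[~np.isnan(cts)]
        if len(amp) == 0:
            flag, mean_ct = ABSENT, np.nan
        elif len(amp) == 1 and len(cts) > 1:
            flag, mean_ct = FAIL_SINGLE, float(amp[0])
        elif len(amp) > 1 and np.std(amp, ddof=1) > 1.0:
            flag, mean_ct = FAIL_SD, float(amp.mean())
        else:
            flag, mean_ct = PASS, float(amp.mean())
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update({"mean_ct": mean_ct, "n_amplified": int(len(amp)), "qc_flag": flag})
        rows.append(row)
    return pd.DataFrame(rows)


def proportion_durusdinium(
    ct_c: float,
    ct_d: float,
    corr: QpcrCorrections | None = None,
) -> float:
    """Corrected proportion Durusdinium from mean genus CTs.

    copies_X = eff^(-CT_X + f_X) / c_X; proportion = D / (C + D).  A NaN CT
    means that genus did not amplify: only D -> 1, only C -> 0 (bleached
    larvae typically carry no Durusdinium at all), neither -> NaN.
    """
    corr = corr or QpcrCorrections()
    c_amp = not np.isnan(ct_c)
    d_amp = not np.isnan(ct_d)
    if not c_amp and not d_amp:
        return np.nan
    if not d_amp:
        return 0.0
    if not c_amp:
        return 1.0
    copies_c = corr.efficiency ** (-ct_c + corr.f_c) / corr.c_c
    copies_d = corr.efficiency ** (-ct_d + corr.f_d) / corr.c_d
    return float(copies_d / (copies_c + copies_d))


def summarize_colony(
    branch_props: pd.DataFrame,
    min_replicates: int = 1,
) -> pd.DataFrame:
    """Mean proportion Durusdinium per colony over retained branch replicates.

    `branch_props` has columns colony, proportion, qc_ok (bool); branches
    whose QC failed are excluded, and a colony with fewer than
    `min_replicates` retained branches is flagged missing (NaN mean).
    """
    rows = []
    for colony, sub in branch_props.groupby("colony", sort=True):
        ok = sub[sub["qc_ok"] & sub["proportion"].notna()]
        n = len(ok)
        mean = float(ok["proportion"].mean()) if n >= min_replicates else np.nan
        rows.append({"colony": colony, "mean_proportion": mean, "n_replicates": n,
                     "missing": n < min_replicates})
    return pd.DataFrame(rows)


def symbiont_profiles(
    qpcr_table: pd.DataFrame,
    corr: QpcrCorrections | None = None,
    min_replicates: int = 1,
) -> pd.DataFrame:
    """Full pipeline: QC replicates, branch proportions, colony means.

    `qpcr_table` is long format with columns colony, branch, assay
    ("C"/"D"; other assays such as a host marker are carried but unused),
    tech_rep, ct (NaN = no amplification).
    """
    sub = qpcr_table[qpcr_table["assay"].isin(["C", "D"])]
    qc = qc_replicates(sub[["colony", "branch", "assay", "tech_rep", "ct"]])
    wide = qc.pivot(index=["colony", "branch"], columns="assay",
                    values=["mean_ct", "qc_flag"])
    rows = []
    for (colony, branch), r in wide.iterrows():
        flag_c = r.get(("qc_flag", "C"), ABSENT)
        flag_d = r.get(("qc_flag", "D"), ABSENT)
        qc_ok = flag_c in (PASS, ABSENT) and flag_d in (PASS, ABSENT)
        ct_c = r.get(("mean_ct", "C"), np.nan)
        ct_d = r.get(("mean_ct", "D"), np.nan)
        prop = proportion_durusdinium(ct_c, ct_d, corr) if qc_ok else np.nan
        rows.append({"colony": colony, "branch": branch, "proportion": prop,
                     "qc_ok": qc_ok, "flag_c": flag_c, "flag_d": flag_d})
    branch_props = pd.DataFrame(rows)
    colony_means = summarize_colony(branch_props, min_replicates)
    return colony_means.merge(
        branch_props.groupby("colony").size().rename("n_branches"), on="colony"
    )
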