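"""End-to-end orchestration: per-genotype pipelines and comparison reports.

Ties the stages together for the cis-vs-trans study design: run the
voltage-clamp pipeline for each packaged genotype, collect tidy feature
tables keyed by group, and produce the group summaries and statistical
comparisons defined in :mod:`phaseclamp.stats`.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import pandas as pd

from . import stats, vclamp
from .params import CellParams, GENOTYPES, VoltageStepProtocol
from .synth import simulate_vc_recording


def analyze_genotype_vc(
    label: str,
    protocol: Optional[VoltageStepProtocol] = None,
    cell: Optional[CellParams] = None,
    noise_sd_pA: float = 0.0,
    fs_hz: float = 20_000.0,
    fit_kinetics: bool = True,
) -> dict:
    """Simulate and fully analyze one packaged genotype's VC recording.

    Returns the :func:`phaseclamp.vclamp.analyze_recording` result dict
    (I–V table, maxima, per-step kinetics).
    """
    if label not in GENOTYPES:
        raise KeyError(f"unknown genotype {label!r}; packaged: {sorted(GENOTYPES)}")
    protocol = protocol or VoltageStepProtocol()
    cell = cell or CellParams()
    sweeps = simulate_vc_recording(
        GENOTYPES[label], cell, protocol, block_fraction=1.0,
        noise_sd_pA=noise_sd_pA, fs_hz=fs_hz,
    )
    res = vclamp.analyze_recording(
        sweeps, protocol, cell.capacitance_pF, fit_kinetics=fit_kinetics
    )
    res["label"] = label
    return res


def genotype_iv_table(
    labels: Sequence[str] = ("WT", "A561T_cis", "A561T_trans", "N996I_cis", "N996I_trans"),
    **kwargs,
) -> pd.DataFrame:
    """Tidy I–V summary (one row per genotype)."""
    rows = []
    for label in labels:
        res = analyze_genotype_vc(label, fit_kinetics=False, **kwargs)
        rows.append(
            {
                "genotype": label,
                "max_tail_density_pA_per_pF": res["max_tail_density"],
                "v_max_steady_mV": res["v_max_steady"],
                "max_steady_density_pA_per_pF": res["max_steady_density"],
            }
        )
    return pd.DataFrame(rows)


def activation_tau_at(
    label: str,
    voltage_mV: float = -30.0,
    protocol: Optional[VoltageStepProtocol] = None,
    cell: Optional[CellParams] = None,
    fs_hz: float = 20_000.0,
) -> float:
    """Fitted activation τ (ms) of one genotype at one step voltage.

    Simulates and fits only the requested step level.
    """
    protocol = protocol or VoltageStepProtocol()
    cell = cell or CellParams()
    if voltage_mV not in protocol.step_levels_mV:
        raise ValueError(f"{voltage_mV} mV is not a protocol step level")
    sweeps = simulate_vc_recording(
        GENOTYPES[label], cell, protocol, fs_hz=fs_hz,
        step_levels_mV=[voltage_mV],
    )
    sub = vclamp.subtract_drug(sweeps[0].pre, sweeps[0].post)
    fit = vclamp.fit_activation(
        sub.trace, (protocol.step_start_s, protocol.step_end_s)
    )
    return fit.tau_ms


def cis_trans_acceleration(
    mutation: str, voltage_mV: float = -30.0, **kwargs
) -> float:
    """Percent activation speed-up of the cis line vs its trans counterpart.

    Defined as 100·(τ_trans − τ_cis)/τ_trans at the given step voltage.
    """
    tau_cis = activation_tau_at(f"{mutation}_cis", voltage_mV, **kwargs)
    tau_trans = activation_tau_at(f"{mutation}_trans", voltage_mV, **kwargs)
    return 100.0 * (tau_trans - tau_cis) / tau_trans


def build_comparison_report(
    values: pd.DataFrame,
    design: pd.DataFrame,
    value_cols: Sequence[str],
    id_col: str = "id",
    group_col: str = "group",
) -> Dict[str, pd.DataFrame]:
    """Group summaries and comparisons for measured feature tables.

    ``values`` holds one row per cell/well with an ``id_col``; ``design``
    maps ids to genotype-phase groups. Two groups are compared with the
    t-test, three with the ANOVA/Tukey decision tree.
    """
    df = values.merge(design[[id_col, group_col]], on=id_col, how="inner")
    groups = sorted(df[group_col].unique())
    summaries, comparisons = [], []
    for col in value_cols:
        by_group = {g: df.loc[df[group_col] == g, col].dropna() for g in groups}
        for g, x in by_group.items():
            s = stats.summarize_group(g, x)
            summaries.append(
                {"feature": col, "group": g, "n": s.n, "mean": s.mean, "sem": s.sem}
            )
        if len(groups) == 2:
            res = [stats.compare_two_groups(*by_group.values(), labels=groups)]
        elif len(groups) == 3:
            tree = stats.compare_three_groups(by_group)
            res = [tree["anova"], *tree["tukey"], *tree["pairwise"]]
        else:
            raise ValueError("report supports 2- or 3-group designs")
        frame = stats.comparisons_to_frame(res)
        frame.insert(0, "feature", col)
        comparisons.append(frame)
    return {
        "summaries": pd.DataFrame(summaries),
        "comparisons": pd.concat(comparisons, ignore_index=True),
    }
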