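"""End-to-end orchestration across experiments and group statistics.

``run_full_analysis`` fits every experiment with
:class:`~pylorhythm.model.ThermalResponseModel`, isolates failures, and
assembles cohort-level blocks: paired saline-vs-Cs comparisons of Q10, jag
probabilities and frequency change; a three-condition repeated-measures
ANOVA with Tukey HSD when saline/Cs/Cs+PTX are all present; and the
phase-slope battery with a Bonferroni multiplier taken from the number of
tests actually run.  The JSON report is byte-reproducible: keys sorted and
floats rounded to 12 significant digits.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import phase as _p
from . import stats as _s
from .config import RunConfig
from .io import ExperimentRecord
from .model import ThermalResponseModel, ThermalResponseResults

logger = logging.getLogger("pylorhythm")


@dataclass
class AnalysisReport:
    config: RunConfig
    results: dict = field(default_factory=dict)      # key -> per-experiment dict
    group: dict = field(default_factory=dict)        # figure-style blocks
    errors: dict = field(default_factory=dict)       # key -> error message
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": self.config.__dict__ | {"hold_targets": list(self.config.hold_targets)},
            "experiments": self.results,
            "group": self.group,
            "errors": self.errors,
            "provenance": self.provenance,
        }
        text = json.dumps(_round_floats(payload), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _round_floats(obj):
    """Round every float to 12 significant digits for stable serialisation."""
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        if math.isfinite(v):
            return float(f"{v:.12g}")
        return None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _paired_block(pairs: dict[str, dict[str, float]], a: str, b: str,
                  alpha: float) -> dict | None:
    """Normality-gated paired test over experiments holding both conditions."""
    xs, ys, keys = [], [], []
    for key, vals in sorted(pairs.items()):
        if a in vals and b in vals and vals[a] is not None and vals[b] is not None:
            xs.append(vals[a])
            ys.append(vals[b])
            keys.append(key)
    if len(xs) < 3:
        return None
    try:
        cmp = _s.normality_gated_paired_test(xs, ys, alpha, a, b)
    except ValueError as exc:
        return {"error": str(exc), "n": len(xs)}
    return {
        "test": cmp.test_name, "statistic": cmp.statistic, "p": cmp.p,
        "n": cmp.n, "normality_p": cmp.normality_p,
        f"mean_{a}": cmp.mean_a, f"mean_{b}": cmp.mean_b,
        "experiments": keys, "alpha": alpha,
    }


def run_full_analysis(
    config: RunConfig,
    experiments: Sequence[ExperimentRecord] | dict[str, ExperimentRecord],
) -> AnalysisReport:
    """Fit every experiment and assemble the cohort report.

    ``experiments`` may be a sequence or a mapping of key -> record; records
    of the same animal under different conditions should share a
    ``metadata['animal']`` id so they pair up in the group statistics.  A
    failing experiment is recorded under ``errors`` and the rest continue;
    zero analysable experiments is an error.
    """
    if isinstance(experiments, dict):
        items = list(experiments.items())
    else:
        items = [(rec.metadata.get("id", f"exp{i:02d}"), rec)
                 for i, rec in enumerate(experiments)]
    if not items:
        raise ValueError("no experiments provided")

    report = AnalysisReport(config=config)
    fitted: dict[str, ThermalResponseResults] = {}
    for key, rec in items:
        try:
            res = ThermalResponseModel(rec, config).fit()
        except Exception as exc:  # isolate the failing experiment
            logger.warning("experiment %s failed: %s", key, exc)
            report.errors[key] = f"{type(exc).__name__}: {exc}"
            continue
        fitted[key] = res
        report.results[key] = res.to_dict()
    if not fitted:
        raise ValueError("zero analyzable experiments")

    alpha = config.alpha
    # values per animal per condition
    by_animal: dict[str, dict[str, ThermalResponseResults]] = {}
    for key, res in fitted.items():
        animal = str(res.model.experiment.metadata.get("animal", key))
        by_animal.setdefault(animal, {})[res.condition] = res

    def pick(fn) -> dict[str, dict[str, float]]:
        return {
            animal: {cond: fn(res) for cond, res in conds.items()}
            for animal, conds in by_animal.items()
        }

    group: dict = {}
    q10s = pick(lambda r: r.q10.Q10 if r.q10 else None)
    jag_dec = pick(lambda r: r.jag.p_dec_given_inc)
    jag_inc = pick(lambda r: r.jag.p_inc_given_stable)
    fchange = pick(lambda r: r.frequency_change())

    for name, vals in (
        ("fig1e_q10_saline_vs_cs", q10s),
        ("fig1f_freq_change_saline_vs_cs", fchange),
        ("fig3d_p_dec_saline_vs_cs", jag_dec),
        ("fig3e_p_inc_saline_vs_cs", jag_inc),
    ):
        block = _paired_block(vals, "saline", "Cs", alpha)
        if block is not None:
            group[name] = block

    # three-condition RM-ANOVA blocks (frequency change, jag probabilities)
    conds3 = ("saline", "Cs", "Cs+PTX")
    for name, vals in (
        ("fig4c_freq_change_rm_anova", fchange),
        ("fig4d_p_dec_rm_anova", jag_dec),
        ("fig4e_p_inc_rm_anova", jag_inc),
    ):
        rows = {
            animal: [v[c] for c in conds3]
            for animal, v in sorted(vals.items())
            if all(c in v and v[c] is not None for c in conds3)
        }
        if len(rows) >= 3:
            tbl = pd.DataFrame.from_dict(rows, orient="index", columns=list(conds3))
            res = _s.rm_anova_tukey(tbl)
            group[name] = {
                "F": res.F, "df": [res.df_effect, res.df_error], "p": res.p,
                "n": len(rows),
                "tukey": [
                    {"pair": [t.cond_a, t.cond_b], "mean_diff": t.mean_diff,
                     "q": t.q, "p": t.p}
                    for t in res.tukey
                ],
            }

    # phase-slope battery: one test per (event, condition) with >= 3 slopes
    slope_sets: dict[tuple[str, str], list[float]] = {}
    for res in fitted.values():
        for ev, s in res.phase_slopes.items():
            slope_sets.setdefault((ev, res.condition), []).append(s.slope_per_10C)
    testable = {k: v for k, v in slope_sets.items() if len(v) >= 3}
    n_tests = len(testable) if testable else config.n_phase_tests
    slope_block = {}
    for (ev, cond), slopes in sorted(testable.items()):
        try:
            t = _p.group_slope_test(slopes, n_tests=n_tests, alpha=alpha)
        except ValueError as exc:
            slope_block[f"{ev}_{cond}"] = {"error": str(exc), "n": len(slopes)}
            continue
        slope_block[f"{ev}_{cond}"] = {
            "test": t.test_name, "statistic": t.statistic,
            "p_raw": t.p_raw, "p_adjusted": t.p_adjusted,
            "n": t.n, "normality_p": t.normality_p, "n_tests": t.n_tests,
            "mean_slope_per_10C": float(np.mean(slopes)),
        }
    if slope_block:
        group["fig6_phase_slopes"] = slope_block

    report.group = group
    report.provenance = {
        "package": "pylorhythm",
        "version": _version,
        "rng_seed": config.rng_seed,
        "n_experiments": len(items),
        "n_fitted": len(fitted),
    }
    return report
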