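"""The software robot: score candidate models, pick the minimum-FSE one.

Orchestrates the loop the automated selector runs: feed each candidate
model's (AIC, CS, MSE) triple through the fuzzy system, collect the
defuzzified FSE values, and select the model with the lowest score.
Diagnostic rows ("no rule fired") are flagged, ranked last and excluded
from selection instead of aborting the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .criteria import read_criteria_table
from .fis import MamdaniFIS, NoRuleFired
from .popk import CORRECTIONS, EvaluationInputs, build_reference_fis, evaluate_model

logger = logging.getLogger("fuzzpk")


@dataclass
class EvaluationTable:
    """Per-model evaluation results plus the selected best model.

    ``rows`` preserves the input order and mirrors the criteria table's
    columns plus ``fse``, ``rank`` and a ``diagnostic`` flag; ``metadata``
    records everything needed to reproduce the run (defuzzifier, rule
    mode, out-of-range policy, configuration hash).
    """

    rows: pd.DataFrame
    best_model_id: object
    metadata: dict = field(default_factory=dict)

    def report(self) -> str:
        """Human-readable ranking report."""
        lines = ["Fuzzy evaluation of candidate PopPK models",
                 "=" * 44]
        ranked = self.rows.sort_values("rank")
        for _, r in ranked.iterrows():
            if r["diagnostic"]:
                lines.append(f"  model {r['model_id']}: no rule fired (diagnostic)")
            else:
                lines.append(f"  rank {int(r['rank'])}: model {r['model_id']} "
                             f"FSE={r['fse']:.1f} "
                             f"(AIC={r['aic']:.4g}, CS={r['cs']:.4g}, MSE={r['mse']:.4g})")
        lines.append(f"best model: {self.best_model_id}")
        for k, v in self.metadata.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines)


def find_lowest(values) -> int:
    """Index of the minimum value; ties broken by the earliest index."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot select the lowest of an empty collection")
    return int(np.argmin(arr))


def evaluate_all(criteria_rows: pd.DataFrame, fis: MamdaniFIS,
                 metadata: dict | None = None) -> EvaluationTable:
    """Score every criteria row through the fuzzy system and rank.

    ``criteria_rows`` needs columns model_id, aic, cs, mse (extras carried
    through). Rows where no rule fires receive NaN FSE, a diagnostic flag
    and the last ranks.
    """
    if len(criteria_rows) == 0:
        raise ValueError("criteria table is empty")
    df = criteria_rows.copy().reset_index(drop=True)
    fses: list[float] = []
    diags: list[bool] = []
    for _, row in df.iterrows():
        inputs = EvaluationInputs(aic=row["aic"], cs=row["cs"], mse=row["mse"])
        try:
            fses.append(evaluate_model(fis, inputs))
            diags.append(False)
        except NoRuleFired:
            logger.warning("model %s: no rule fired for (AIC=%g, CS=%g, MSE=%g)",
                           row["model_id"], inputs.aic, inputs.cs, inputs.mse)
            fses.append(float("nan"))
            diags.append(True)
    df["fse"] = fses
    df["diagnostic"] = diags
    # NaNs (diagnostics) sort last; ties keep input order
    order = np.argsort(np.where(df["diagnostic"], np.inf, df["fse"]), kind="stable")
    ranks = np.empty(len(df), dtype=int)
    ranks[order] = np.arange(1, len(df) + 1)
    df["rank"] = ranks
    valid = df[~df["diagnostic"]]
    if len(valid) == 0:
        raise NoRuleFired("no rule fired for any candidate model")
    best_id = valid.iloc[find_lowest(valid["fse"].to_numpy())]["model_id"]
    n_ties = int((valid["fse"] == valid["fse"].min()).sum())
    meta = dict(metadata or {})
    meta.setdefault("config_hash", fis.config_hash())
    meta.setdefault("defuzzifier", fis.options.defuzzifier)
    meta.setdefault("out_of_range", fis.options.out_of_range)
    if n_ties > 1:
        meta["tie"] = f"{n_ties} models share the minimum FSE; earliest row selected"
        logger.warning("FSE tie among %d models; earliest row wins", n_ties)
    return EvaluationTable(rows=df, best_model_id=best_id, metadata=meta)


def run_pipeline(criteria_csv, out_dir, rule_mode: str = "corrected",
                 defuzzifier: str = "discretized_centroid",
                 out_of_range: str = "saturate_extremes",
                 fis_config=None, seed: int | None = None) -> EvaluationTable:
    """Criteria CSV -> results CSV + ranking report + run log.

    Writes ``results.csv`` (input columns + fse/rank), ``report.txt`` and
    ``run.json`` (policies, config hash, applied rulebase corrections,
    seed) under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = read_criteria_table(criteria_csv)
    if fis_config is not None:
        fis = MamdaniFIS.load(fis_config).with_options(
            defuzzifier=defuzzifier, out_of_range=out_of_range)
        corrections: list[dict] = []
        rule_mode = "custom-config"
    else:
        fis = build_reference_fis(mode=rule_mode, defuzzifier=defuzzifier,
                                  out_of_range=out_of_range)
        corrections = ([c.__dict__ for c in CORRECTIONS]
                       if rule_mode == "corrected" else [])
    table = evaluate_all(df, fis, metadata={"rule_mode": rule_mode, "seed": seed})
    table.rows.to_csv(out / "results.csv", index=False)
    (out / "report.txt").write_text(table.report() + "\n")
    with open(out / "run.json", "w") as fh:
        json.dump({"metadata": table.metadata,
                   "best_model_id": str(table.best_model_id),
                   "corrections_applied": corrections}, fh, indent=2, default=str)
    logger.info("pipeline complete: best model %s (results in %s)",
                table.best_model_id, out)
    return table
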