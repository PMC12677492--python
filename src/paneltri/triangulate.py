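"""Seven-model triangulation battery, evidence table and verdict.

Under a hypothesized *true increasing effect* of X on Y the models predict
signs (+ positive, - negative):

====== =============================================================== ====
model  specification                                                   sign
====== =============================================================== ====
1      RI-CLPM cross-lag (within-person residual, t -> t+1)              +
2      time-reversed RI-CLPM concurrent path (adjusting for later Y)     -
3      LCSM coupling (X level -> latent change in Y)                     +
4      multilevel y_c(t+1) ~ x_c(t) + y_c(t)                             +
5      multilevel y_c(t) ~ x_c(t) + y_c(t+1)                             -
6      multilevel (y(t+1) - y(t)) ~ x_c(t)                               +
7      MoSLA: no cross paths at all; evidence is its FIT adequacy       n/a
====== =============================================================== ====

The verdict aggregates with equal weights by default: *supported* when at
least five of the estimable models 1-6 carry the predicted sign
significantly and the MoSLA does not fit adequately; *contradicted* when
at least three carry the opposite sign significantly; otherwise
*inconclusive*.  These thresholds are this package's operationalization of
informal evidence weighing; they are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import centered_regression as cr
from . import model_builders as mb
from . import sem_core
from .panel import PanelDataset

SCHEMA_VERSION = "1"

#: predicted sign of the focal coefficient under "X truly increases Y"
SIGN_PREDICTIONS: dict[int, str] = {1: "+", 2: "-", 3: "+", 4: "+", 5: "-", 6: "+", 7: "n/a"}

PREDICTION_RATIONALE: dict[int, str] = {
    1: "more water at t means more weight at t+1, holding weight at t fixed",
    2: "to reach the same later outcome, a high concurrent predictor must have "
       "compensated for a LOW earlier outcome",
    3: "a true increasing effect raises subsequent latent change in the outcome",
    4: "within-person prospective effect, person-mean-centered analogue of model 1",
    5: "within-person time-reversed analogue of model 2",
    6: "crude effect on the raw change score is positive under a true increase",
    7: "fit-based: adequate MoSLA fit means the data are compatible with NO "
       "direct effects at all",
}


@dataclass
class BatteryConfig:
    """Tunable switches of the battery run."""

    lag_constrained: bool = True
    standardize: bool = True
    chi2_scale: str = "n-1"
    cfi_min: float = 0.95
    rmsea_max: float = 0.06
    n_starts: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "BatteryConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class EvidenceRow:
    model_id: int
    estimable: bool
    estimate: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    p_value: float | None = None
    sign_category: str | None = None      # '+', '-', '0'
    predicted_sign: str = ""
    consistent: bool | None = None        # None for null / model 7 / not estimable
    note: str = ""


@dataclass
class EvidenceTable:
    direction: str                        # 'xy' or 'yx'
    rows: list[EvidenceRow]
    mosla_fit: dict | None
    mosla_adequate: bool | None
    verdict: str = ""

    def row(self, model_id: int) -> EvidenceRow:
        for r in self.rows:
            if r.model_id == model_id:
                return r
        raise KeyError(model_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows]).assign(direction=self.direction)


def _categorize(est: float, lo: float, hi: float) -> str:
    if lo > 0:
        return "+"
    if hi < 0:
        return "-"
    return "0"


def _row_from_ci(model_id: int, est: float, lo: float, hi: float, p: float) -> EvidenceRow:
    cat = _categorize(est, lo, hi)
    pred = SIGN_PREDICTIONS[model_id]
    consistent: bool | None
    if cat == "0":
        consistent = None
    else:
        consistent = cat == pred
    return EvidenceRow(model_id=model_id, estimable=True, estimate=est, ci_lo=lo,
                       ci_hi=hi, p_value=p, sign_category=cat,
                       predicted_sign=pred, consistent=consistent)


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

def run_battery(panel: PanelDataset, direction: str = "xy",
                config: BatteryConfig | None = None,
                _shared: dict | None = None):
    """Fit all seven models in one direction; returns (EvidenceTable, details).

    ``details`` maps model ids to the underlying :class:`~paneltri.sem_core.SemFit`
    objects (models 1-3, 7) or coefficient tables (models 4-6).  Individual
    model failures degrade to non-estimable rows; only total failure raises.
    """
    cfg = config or BatteryConfig()
    if direction not in ("xy", "yx"):
        raise ValueError("direction must be 'xy' or 'yx'")
    T = panel.T
    layout = mb.PanelLayout(T=T)
    oriented = layout if direction == "xy" else layout.swapped()
    wide = panel.to_wide(dropna=True)
    moments = sem_core.SampleMoments.from_data(wide)
    details: dict = {} if _shared is None else _shared
    rows: list[EvidenceRow] = []
    failures: dict[int, str] = {}

    def sem_fit(key, spec):
        if key not in details:
            details[key] = sem_core.fit(spec, moments, n_starts=cfg.n_starts,
                                        seed=cfg.seed, chi2_scale=cfg.chi2_scale)
        return details[key]

    # model 1: RI-CLPM (direction-symmetric fit, direction-specific coefficient)
    try:
        f1 = sem_fit("riclpm", mb.build_riclpm(layout, lag_constrained=cfg.lag_constrained))
        tgt, src = mb.riclpm_crosslag_labels(layout, direction=direction)[0]
        est, se = f1.std_path(tgt, src)
        raw_lab = "c_xy" if direction == "xy" else "c_yx"
        praw = float(f1.param_table().set_index("label").loc[raw_lab, "p_value"])
        rows.append(_row_from_ci(1, est, est - 1.96 * se, est + 1.96 * se, praw))
        details[("coef", 1, direction)] = (est, se)
    except Exception as exc:  # pragma: no cover - degradation path
        failures[1] = str(exc)
        rows.append(EvidenceRow(1, False, predicted_sign="+", note=str(exc)))

    # model 2: time-reversed RI-CLPM, per direction
    try:
        spec2 = mb.build_riclpm_reversed(oriented)
        f2 = sem_fit(("riclpm_rev", direction), spec2)
        tgt, src = f"r_{oriented.y_names[0]}", f"r_{oriented.x_names[0]}"
        est, se = f2.std_path(tgt, src)
        praw = float(f2.param_table().set_index("label").loc["d_1", "p_value"])
        rows.append(_row_from_ci(2, est, est - 1.96 * se, est + 1.96 * se, praw))
    except Exception as exc:
        failures[2] = str(exc)
        rows.append(EvidenceRow(2, False, predicted_sign="-", note=str(exc)))

    # model 3: LCSM (direction-symmetric fit)
    try:
        f3 = sem_fit("lcsm", mb.build_lcsm(layout))
        tgt = f"d_{oriented.y_names[1]}"
        src = oriented.x_names[0]
        est, se = f3.std_path(tgt, src)
        raw_lab = mb.lcsm_coupling_labels(direction)
        praw = float(f3.param_table().set_index("label").loc[raw_lab, "p_value"])
        rows.append(_row_from_ci(3, est, est - 1.96 * se, est + 1.96 * se, praw))
    except Exception as exc:
        failures[3] = str(exc)
        rows.append(EvidenceRow(3, False, predicted_sign="+", note=str(exc)))

    # models 4-6: person-mean-centered multilevel regressions
    try:
        centered = cr.person_mean_center(panel)
    except Exception as exc:
        centered = None
        for mid in (4, 5, 6):
            failures[mid] = str(exc)
            rows.append(EvidenceRow(mid, False, predicted_sign=SIGN_PREDICTIONS[mid], note=str(exc)))
    if centered is not None:
        for mid, runner in ((4, cr.run_model4), (5, cr.run_model5), (6, cr.run_model6)):
            try:
                tab = runner(centered, direction=direction, standardize=cfg.standardize)
                r = tab.loc["x_c_t"]
                rows.append(_row_from_ci(mid, float(r["estimate"]), float(r["ci_lo"]),
                                         float(r["ci_hi"]), float(r["p_value"])))
                details[(mid, direction)] = tab
            except Exception as exc:
                failures[mid] = str(exc)
                rows.append(EvidenceRow(mid, False, predicted_sign=SIGN_PREDICTIONS[mid],
                                        note=str(exc)))

    # model 7: MoSLA adequacy (direction-independent)
    mosla_fit_summary = None
    adequate = None
    try:
        if "mosla" not in details:
            details["mosla"] = sem_core.fit(
                mb.build_mosla(layout), moments, n_starts=cfg.n_starts,
                seed=cfg.seed, chi2_scale=cfg.chi2_scale,
                compute_se=False, standardized=False)
        f7 = details["mosla"]
        mosla_fit_summary = {
            "chi2": f7.chi2, "df": f7.df, "p": f7.p_chi2, "cfi": f7.cfi,
            "tli": f7.tli, "rmsea": f7.rmsea, "rmsea_ci90": list(f7.rmsea_ci90),
            "converged": f7.converged,
        }
        adequate = mosla_adequacy(f7, cfi_min=cfg.cfi_min, rmsea_max=cfg.rmsea_max)
        rows.append(EvidenceRow(7, True, predicted_sign="n/a",
                                note="adequate fit" if adequate else "inadequate fit"))
    except Exception as exc:
        failures[7] = str(exc)
        rows.append(EvidenceRow(7, False, predicted_sign="n/a", note=str(exc)))

    if len(failures) == 7:
        raise RuntimeError(f"all battery models failed: {failures}")

    table = EvidenceTable(direction=direction, rows=rows,
                          mosla_fit=mosla_fit_summary, mosla_adequate=adequate)
    table.verdict = aggregate_evidence(table)
    return table, details


def run_battery_both(panel: PanelDataset, config: BatteryConfig | None = None):
    """Battery in both directions, re-using the direction-symmetric fits."""
    shared: dict = {}
    t_xy, _ = run_battery(panel, "xy", config, _shared=shared)
    t_yx, _ = run_battery(panel, "yx", config, _shared=shared)
    return {"xy": t_xy, "yx": t_yx}, shared


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_evidence(table: EvidenceTable, weights: list[float] | None = None) -> str:
    """Equal-weight (or weighted) verdict from the evidence table.

    supported   — consistent weight >= 5/6 of estimable weight among models
                  1-6 AND the MoSLA does not fit adequately;
    contradicted — significantly-opposite weight >= 1/2 of estimable weight;
    inconclusive — otherwise.
    """
    rows = [table.row(m) for m in range(1, 7)]
    if weights is None:
        w = [1.0] * 6
    else:
        if len(weights) != 6:
            raise ValueError("weights must give one value per model 1-6")
        w = [float(x) for x in weights]
    est_rows = [(r, wi) for r, wi in zip(rows, w) if r.estimable]
    if len(est_rows) < 2:
        raise ValueError("need at least two estimable models among 1-6")
    total = sum(wi for _, wi in est_rows)
    consistent = sum(wi for r, wi in est_rows if r.consistent is True)
    inconsistent = sum(wi for r, wi in est_rows if r.consistent is False)
    mosla_ok = bool(table.mosla_adequate)
    if consistent >= (5.0 / 6.0) * total - 1e-12 and not mosla_ok:
        return "supported"
    if inconsistent >= 0.5 * total - 1e-12:
        return "contradicted"
    return "inconclusive"


def mosla_adequacy(fit: "sem_core.SemFit", cfi_min: float = 0.95,
                   rmsea_max: float = 0.06) -> bool:
    """Adequate iff CFI >= cfi_min and RMSEA <= rmsea_max (closed thresholds)."""
    if not fit.converged:
        raise ValueError("MoSLA fit did not converge")
    return bool(fit.cfi >= cfi_min and fit.rmsea <= rmsea_max)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_MARKS = {True: "✓", False: "✗", None: "·"}


def results_payload(tables: dict[str, EvidenceTable], meta: dict | None = None) -> dict:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "meta": dict(sorted((meta or {}).items())),
        "directions": {},
    }
    for direction, table in sorted(tables.items()):
        payload["directions"][direction] = {
            "verdict": table.verdict,
            "mosla_adequate": table.mosla_adequate,
            "mosla_fit": table.mosla_fit,
            "models": [asdict(r) for r in table.rows],
        }
    return payload


def write_report(results: dict | dict[str, EvidenceTable], path, format: str = "json"):
    """Serialize battery results; json round-trips losslessly."""
    if results and all(isinstance(v, EvidenceTable) for v in results.values()):
        results = results_payload(results)  # type: ignore[arg-type]
    if format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        rows = []
        for direction, block in results["directions"].items():
            for r in block["models"]:
                rows.append({"direction": direction, **r})
        pd.DataFrame(rows).to_csv(path, index=False)
    elif format == "text":
        with open(path, "w") as fh:
            fh.write(render_text_report(results))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def render_text_report(results: dict) -> str:
    lines = [f"paneltri evidence report (schema {results.get('schema_version', '?')})"]
    for direction, block in results["directions"].items():
        arrow = "X -> Y" if direction == "xy" else "Y -> X"
        lines.append("")
        lines.append(f"direction {arrow}: verdict = {block['verdict']}")
        lines.append(f"{'model':>5}  {'pred':>4}  {'obs':>4}  {'estimate':>9}  mark")
        for r in block["models"]:
            mid = r["model_id"]
            if mid == 7:
                mark = _MARKS[None]
                fitinfo = block.get("mosla_fit") or {}
                est = f"CFI={fitinfo.get('cfi', float('nan')):.2f}" if fitinfo else "-"
                lines.append(f"{mid:>5}  {'n/a':>4}  {('fit' if r['estimable'] else '-'):>4}  "
                             f"{est:>9}  {mark} {r['note']}")
                continue
            mark = _MARKS[r["consistent"]]
            est = "-" if r["estimate"] is None else f"{r['estimate']:+.3f}"
            obs = r["sign_category"] or "-"
            lines.append(f"{mid:>5}  {r['predicted_sign']:>4}  {obs:>4}  {est:>9}  {mark}")
    lines.append("")
    lines.append("marks: ✓ consistent with a true increasing effect, "
                 "✗ significantly opposite, · null/not applicable")
    return "\n".join(lines) + "\n"
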