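"""End-to-end orchestration: measurement over case directories and the full
statistical analysis of a cohort table.

``CohortAnalysis`` is the model-style entry point: construct it from a
cohort DataFrame plus an :class:`AnalysisConfig`, call :meth:`fit`, and the
returned :class:`CohortResults` carries the five report tables (demographics,
intergroup comparison, correlations, stepwise regression, ROC/triage) plus
run metadata; ``to_dir`` writes them as CSV/JSON. Every number in a rendered
table is re-derivable from the stored raw intermediates, and identical
input + config produces a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, reference, stats
from .cephalometry import compute_ceph_record
from .errors import CephscreenError, DegenerateSampleError, SchemaError
from .io import load_mask, write_cohort_csv
from .landmarks import LandmarkSet
from .morphometry import compute_airway_params
from .roc import auc_ci, evaluate_triage, roc_points, triage_cutoffs, youden_cutoff
from .stepwise import StepwiseOLS

log = logging.getLogger("cephscreen")

#: ROC predictor panels per outcome ("MLRM" = fitted stepwise model).
ROC_PANELS = {
    "SASN": ("MLRM", "SPAS", "MPAS", "IPAS", "GoGn"),
    "RSAV": ("MLRM", "IPAS", "BH", "SPAS", "MPAS", "GoGn"),
}


@dataclass
class AnalysisConfig:
    """Thresholds, selection criteria and targets for one analysis run."""

    amin_cut: float = reference.SASN_AMIN_CUT
    vpas_cut: float = reference.RSAV_VPAS_CUT
    p_enter: float = 0.05
    p_remove: float = 0.10
    sens_target: float = 0.90
    spec_target: float = 0.90
    seed: int = 0
    candidates: tuple[str, ...] = tuple(reference.LATERAL_2D_CANDIDATES)

    def __post_init__(self):
        if self.amin_cut <= 0 or self.vpas_cut <= 0:
            raise ValueError("grouping thresholds must be positive")
        if not self.p_enter < self.p_remove:
            raise ValueError("p_enter must be < p_remove")
        if not (0 < self.sens_target < 1 and 0 < self.spec_target < 1):
            raise ValueError("triage targets must lie in (0, 1)")
        self.candidates = tuple(self.candidates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# measurement stage
# --------------------------------------------------------------------------

def run_measure(case_dir: str | Path) -> tuple[pd.DataFrame, list[dict]]:
    """Measure every case (mask + landmark JSON sharing a stem) in a directory.

    Returns ``(table, errors)``: one row per successful case; failures are
    recorded per case and the run continues.
    """
    case_dir = Path(case_dir)
    masks = sorted(
        [p for p in case_dir.iterdir()
         if p.name.endswith((".nii", ".nii.gz", ".nrrd"))]
    )
    rows, errors = [], []
    for mask_path in masks:
        stem = mask_path.name
        for suffix in (".nii.gz", ".nii", ".nrrd"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        lm_path = case_dir / f"{stem}.json"
        try:
            if not lm_path.exists():
                raise FileNotFoundError(f"no landmark file {lm_path.name}")
            mask = load_mask(mask_path)
            lms = LandmarkSet.from_json(lm_path)
            row: dict = {"case": stem}
            row.update(compute_airway_params(mask, lms).to_row())
            row.update(compute_ceph_record(lms).to_row())
            rows.append(row)
        except Exception as exc:  # per-case isolation: log and continue
            log.warning("case %s failed: %s", stem, exc)
            errors.append({"case": stem, "error": str(exc)})
    df = pd.DataFrame(rows)
    return df, errors


# --------------------------------------------------------------------------
# analysis stage
# --------------------------------------------------------------------------

@dataclass
class CohortResults:
    """Report bundle produced by :class:`CohortAnalysis.fit`."""

    demographics: pd.DataFrame
    intergroup: pd.DataFrame
    correlations: pd.DataFrame
    regression: pd.DataFrame
    roc_triage: pd.DataFrame
    models: dict
    rules: dict
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        meta = self.metadata
        lines = [
            f"cephscreen cohort analysis (n={meta.get('n')}, "
            f"config {meta.get('config_hash')})",
            f"SASN: {meta.get('n_sasn')} / RSAV: {meta.get('n_rsav')}",
            "",
            "ROC / triage:",
            self.roc_triage.to_string(index=False, float_format="%.3f"),
        ]
        return "\n".join(lines)

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in (
            ("demographics", self.demographics),
            ("intergroup", self.intergroup),
            ("correlations", self.correlations),
            ("regression", self.regression),
            ("roc_triage", self.roc_triage),
        ):
            table.to_csv(outdir / f"{name}.csv", index=False, float_format="%.6g")
        bundle = {
            "metadata": self.metadata,
            "models": self.models,
            "triage_rules": self.rules,
        }
        with open(outdir / "bundle.json", "w") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)


class CohortAnalysis:
    """Full statistical cascade over a measured cohort table."""

    def __init__(self, cohort: pd.DataFrame, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        required = {"A_min", "V_PAS"}
        missing = required - set(cohort.columns)
        if missing:
            raise SchemaError(f"cohort table lacks columns {sorted(missing)}")
        self.cohort = cohort.reset_index(drop=True).copy()
        if "gender" in self.cohort.columns and "gender_female" not in self.cohort.columns:
            self.cohort["gender_female"] = (
                self.cohort["gender"].astype(str).str.lower().str.startswith("f")
            ).astype(float)

    # -- table builders ------------------------------------------------------

    def _demographics(self, groups) -> pd.DataFrame:
        df = self.cohort
        rows = []
        for tag, flag in (("A", groups.sasn), ("B", groups.rsav)):
            g1, g2 = df[flag], df[~flag]
            row: dict = {"split": tag, "n1": len(g1), "n2": len(g2)}
            if "gender" in df.columns:
                t1 = g1["gender"].eq("m").sum(), g1["gender"].eq("f").sum()
                t2 = g2["gender"].eq("m").sum(), g2["gender"].eq("f").sum()
                try:
                    chi2, p = stats.chi_squared_2x2([list(t1), list(t2)])
                except CephscreenError:
                    chi2, p = np.nan, np.nan
                row.update({"male1": t1[0], "female1": t1[1],
                            "male2": t2[0], "female2": t2[1],
                            "gender_chi2": chi2, "gender_p": p})
            for var in ("age", "BH", "BW", "BMI"):
                if var not in df.columns:
                    continue
                try:
                    res = stats.students_t(g1[var], g2[var])
                    row[f"{var}_mean1"] = res.mean1
                    row[f"{var}_mean2"] = res.mean2
                    row[f"{var}_p"] = res.p_raw
                except CephscreenError:
                    row[f"{var}_p"] = np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def _intergroup(self, groups) -> pd.DataFrame:
        df = self.cohort
        params = [p for p in reference.ALL_PARAMETERS if p in df.columns]
        out: dict[str, list] = {"parameter": params}
        for tag, flag, defining in (("A", groups.sasn, "A_min"),
                                    ("B", groups.rsav, "V_PAS")):
            m1s, s1s, m2s, s2s, ps = [], [], [], [], []
            for p in params:
                g1 = df.loc[flag, p].astype(float)
                g2 = df.loc[~flag, p].astype(float)
                m1s.append(g1.mean())
                s1s.append(g1.std(ddof=1))
                m2s.append(g2.mean())
                s2s.append(g2.std(ddof=1))
                if p == defining:
                    ps.append(np.nan)  # defines the split; not tested
                    continue
                try:
                    ps.append(stats.students_t(g1, g2).p_raw)
                except DegenerateSampleError:
                    ps.append(np.nan)
            ps = np.asarray(ps, dtype=float)
            p_fdr = np.full_like(ps, np.nan)
            finite = np.isfinite(ps)
            if finite.any():
                p_fdr[finite] = stats.bh_adjust(ps[finite])
            out[f"mean_{tag}1"], out[f"sd_{tag}1"] = m1s, s1s
            out[f"mean_{tag}2"], out[f"sd_{tag}2"] = m2s, s2s
            out[f"p_{tag}"], out[f"p_fdr_{tag}"] = ps, p_fdr
            out[f"sig_{tag}"] = p_fdr < stats.ALPHA
        return pd.DataFrame(out)

    def _correlations(self) -> pd.DataFrame:
        df = self.cohort
        params = [p for p in (*reference.ALL_PARAMETERS, "age", "BH", "BW", "BMI")
                  if p in df.columns]
        out: dict[str, list] = {"parameter": []}
        rows: dict[str, dict] = {}
        for target in ("A_min", "V_PAS"):
            rs, ps, cats, names = [], [], [], []
            for p in params:
                if p == target:
                    continue
                try:
                    res = stats.pearson(df[p], df[target])
                    rs.append(res.r)
                    ps.append(res.p_raw)
                    cats.append(res.category)
                except DegenerateSampleError:
                    rs.append(np.nan)
                    ps.append(np.nan)
                    cats.append("")
                names.append(p)
            ps_arr = np.asarray(ps, dtype=float)
            p_fdr = np.full_like(ps_arr, np.nan)
            finite = np.isfinite(ps_arr)
            if finite.any():
                p_fdr[finite] = stats.bh_adjust(ps_arr[finite])
            for i, name in enumerate(names):
                row = rows.setdefault(name, {"parameter": name})
                row[f"r_{target}"] = rs[i]
                row[f"p_{target}"] = ps_arr[i]
                row[f"p_fdr_{target}"] = p_fdr[i]
                row[f"category_{target}"] = cats[i]
        return pd.DataFrame(list(rows.values()))

    def _regressions(self) -> tuple[pd.DataFrame, dict]:
        df = self.cohort
        candidates = [c for c in self.config.candidates if c in df.columns]
        models, frames = {}, []
        for response in ("A_min", "V_PAS"):
            model = StepwiseOLS.from_dataframe(
                df, response, candidates,
                p_enter=self.config.p_enter, p_remove=self.config.p_remove,
            ).fit()
            models[response] = model
            frame = model.to_frame()
            frame.insert(0, "response", response)
            frame["R2"] = model.rsquared
            frame["R2_adj"] = model.rsquared_adj
            frame["F"] = model.fvalue
            frames.append(frame)
        return pd.concat(frames, ignore_index=True), models

    def _roc_triage(self, groups, models) -> tuple[pd.DataFrame, dict]:
        df = self.cohort
        rows, rules = [], {}
        for outcome, labels, response in (("SASN", groups.sasn, "A_min"),
                                          ("RSAV", groups.rsav, "V_PAS")):
            for predictor in ROC_PANELS[outcome]:
                if predictor == "MLRM":
                    scores = models[response].predict(df)
                    name = f"MLRM_{response}"
                elif predictor in df.columns:
                    scores = df[predictor].to_numpy(dtype=float)
                    name = predictor
                else:
                    continue
                curve = roc_points(scores, labels, direction="lower")
                auc = auc_ci(scores, labels, direction="lower")
                cut = youden_cutoff(curve)
                rule = triage_cutoffs(
                    curve, self.config.sens_target, self.config.spec_target,
                    predictor=name)
                ev = evaluate_triage(scores, labels, rule)
                rules[f"{outcome}:{name}"] = rule.to_dict()
                rows.append({
                    "outcome": outcome, "predictor": name,
                    "auc": auc.auc, "auc_ci_low": auc.ci_low,
                    "auc_ci_high": auc.ci_high, "auc_p": auc.p_vs_half,
                    "cutoff": cut.threshold, "sens": cut.sensitivity,
                    "spec": cut.specificity,
                    "balanced_accuracy": 100 * (cut.sensitivity + cut.specificity) / 2,
                    "lower_cutoff": rule.lower, "upper_cutoff": rule.upper,
                    "triage_sens": ev.sensitivity, "triage_spec": ev.specificity,
                    "triage_balanced_accuracy": ev.balanced_accuracy,
                    "deferral_fraction": ev.deferral_fraction,
                })
        return pd.DataFrame(rows), rules

    # -- entry point ---------------------------------------------------------

    def fit(self) -> CohortResults:
        groups = stats.assign_groups(self.cohort, self.config.amin_cut,
                                     self.config.vpas_cut)
        regression, models = self._regressions()
        roc_table, rules = self._roc_triage(groups, models)
        meta = {
            "version": __version__,
            "n": int(len(self.cohort)),
            "n_sasn": groups.counts["A1"],
            "n_rsav": groups.counts["B1"],
            "seed": self.config.seed,
            "config_hash": self.config.hash(),
            "config": asdict(self.config),
        }
        return CohortResults(
            demographics=self._demographics(groups),
            intergroup=self._intergroup(groups),
            correlations=self._correlations(),
            regression=regression,
            roc_triage=roc_table,
            models={k: m.to_dict() for k, m in models.items()},
            rules=rules,
            metadata=meta,
        )


def run_analyze(cohort: pd.DataFrame, config: AnalysisConfig | None = None,
                outdir: str | Path | None = None) -> CohortResults:
    """Fit the full cascade; optionally write the report bundle to ``outdir``."""
    results = CohortAnalysis(cohort, config).fit()
    if outdir is not None:
        results.to_dir(outdir)
    return results


def measure_to_csv(case_dir: str | Path, out_csv: str | Path) -> int:
    """Measure a case directory to one CSV; returns the number of failures."""
    df, errors = run_measure(case_dir)
    write_cohort_csv(df, out_csv)
    if errors:
        err_path = Path(out_csv).with_suffix(".errors.json")
        with open(err_path, "w") as fh:
            json.dump(errors, fh, indent=1)
    return len(errors)
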