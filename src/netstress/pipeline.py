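"""End-to-end orchestration: strengths -> GLM -> follow-ups -> report.

`run_analysis` reproduces the full analysis battery on one cohort: the
primary 2x2 repeated-measures GLM on network strength, within-group simple
effects and between-group contrasts with percent differences, the
covariate-adjusted interaction, delta-strength vs symptom-severity
correlations, the split-half scan-duration GLMs, and (when per-scan
connectivity matrices are available) the mass-univariate nodal exploration
with FDR adjustment.  Output is a deterministic `AnalysisReport` written as
JSON, CSV and a short text summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atlas_io import NetworkAtlas, read_atlas, read_timeseries
from .connectome import (ConnectivityMatrix, correlation_matrix, fisher_z,
                         network_strength, nodal_strength, scan_strength,
                         split_halves)
from .inference import (AnovaResult, CohortTable, EffectContrast,
                        ancova_interaction, correlation_test, duration_analysis,
                        fdr_adjust, group_contrast, mixed_anova_2x2,
                        percent_difference, simple_effect)

log = logging.getLogger("netstress")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis",
           "nodal_exploration", "load_cohort", "strengths_from_timeseries"]

#: severity scores tested against delta strength, with the group they apply to
SEVERITY_SCORES = (
    ("QIDS", "MDD"),
    ("QIDS", "PTSD"),
    ("PCL5_total", "PTSD"),
    ("caps_reexperiencing", "PTSD"),
    ("caps_avoidance", "PTSD"),
    ("caps_negative_mood", "PTSD"),
    ("caps_arousal", "PTSD"),
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs and switches for one analysis run.

    Provide either ``strengths_csv`` (long format: subject, scan_label,
    network, value) or ``timeseries_dir`` + ``atlas_path`` (TSV scans named
    ``<subject>_<scan>.tsv``); ``subjects_csv`` supplies group membership,
    covariates and symptom scores.
    """

    subjects_csv: Optional[str] = None
    strengths_csv: Optional[str] = None
    timeseries_dir: Optional[str] = None
    atlas_path: Optional[str] = None
    network: str = "DMN"
    covariates: tuple[str, ...] = ()
    alpha: float = 0.05
    fdr: bool = True
    split_half: bool = False
    nodal: bool = False
    nodal_condition: str = "post"  # the exploration targets post-stress scans
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.strengths_csv is None and self.timeseries_dir is None:
            raise ValueError("provide strengths_csv or timeseries_dir")
        if self.timeseries_dir is not None and self.atlas_path is None:
            raise ValueError("timeseries input needs atlas_path")
        if self.nodal and self.timeseries_dir is None:
            raise ValueError("nodal exploration needs timeseries input")
        if self.nodal_condition not in ("pre", "post"):
            raise ValueError("nodal_condition must be 'pre' or 'post'")


@dataclass
class AnalysisReport:
    """Everything one run computes, JSON-serializable and deterministic."""

    anova: dict[str, AnovaResult]
    simple_effects: dict[str, dict]
    group_contrasts: dict[str, dict]
    ancova: Optional[AnovaResult]
    severity_correlations: dict[str, dict]
    duration: dict[str, dict[str, AnovaResult]]
    nodal: Optional[pd.DataFrame]
    provenance: dict

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (np.floating, float)):
                return float(x)
            if isinstance(x, (np.integer, int)):
                return int(x)
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="records")
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return {
            "anova": conv(self.anova),
            "simple_effects": conv(self.simple_effects),
            "group_contrasts": conv(self.group_contrasts),
            "ancova": conv(self.ancova),
            "severity_correlations": conv(self.severity_correlations),
            "duration": conv(self.duration),
            "nodal": conv(self.nodal) if self.nodal is not None else None,
            "provenance": conv(self.provenance),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [f"netstress analysis report (v{__version__})", "=" * 40]
        for name, res in self.anova.items():
            lines.append(
                f"{name:>12}: F(1,{res.df2}) = {res.F:.3f}, p = {res.p:.4f}"
            )
        for name, d in self.simple_effects.items():
            lines.append(
                f"simple effect {name}: {d['percent']:.0f}% {d['contrast'].direction}"
                f" (mean diff {d['contrast'].mean_difference:.4f},"
                f" SEM {d['contrast'].sem:.4f}, p = {d['contrast'].p:.3f})"
            )
        for name, d in self.group_contrasts.items():
            lines.append(
                f"group contrast {name}: {d['percent']:.0f}%"
                f" (mean diff {d['contrast'].mean_difference:.4f},"
                f" SEM {d['contrast'].sem:.4f}, p = {d['contrast'].p:.3f})"
            )
        if self.ancova is not None:
            lines.append(
                f"covariate-adjusted interaction: F(1,{self.ancova.df2}) ="
                f" {self.ancova.F:.3f}, p = {self.ancova.p:.4f}"
            )
        for key, c in self.severity_correlations.items():
            lines.append(
                f"delta-strength vs {key}: r = {c['r']:.2f}, n = {c['n']},"
                f" p = {c['p']:.2f}"
            )
        for run, effects in self.duration.items():
            for name, res in effects.items():
                lines.append(
                    f"duration ({run}) {name}: F(1,{res.df2}) = {res.F:.3f},"
                    f" p = {res.p:.4f}"
                )
        if self.nodal is not None:
            surv = int((self.nodal["p_adjusted"] <= self.provenance["alpha"]).sum())
            lines.append(
                f"nodal exploration: {len(self.nodal)} nodes,"
                f" {surv} survive FDR at alpha = {self.provenance['alpha']}"
            )
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        (out / "report.txt").write_text(self.summary())
        if self.nodal is not None:
            self.nodal.to_csv(out / "nodal.csv", index=False)
        return out


def load_cohort(
    subjects_csv: str | Path,
    strengths_csv: str | Path,
    network: str = "DMN",
) -> tuple[CohortTable, pd.DataFrame]:
    """Join a subject table with a long-format strength table.

    Returns the cohort (pre/post strengths) and the raw strength table, which
    may also carry half-scan rows (scan_label ``pre_h1`` etc.) for the
    duration analysis.
    """
    subjects = pd.read_csv(subjects_csv)
    strengths = pd.read_csv(strengths_csv)
    need = {"subject", "scan_label", "value"}
    if not need.issubset(strengths.columns):
        raise ValueError(f"strength table needs columns {sorted(need)}")
    if "network" in strengths.columns:
        strengths = strengths[strengths["network"] == network]
    if "subject_id" not in subjects.columns:
        raise ValueError("subject table needs a subject_id column")
    wide = strengths.pivot_table(index="subject", columns="scan_label",
                                 values="value", aggfunc="first")
    for scan in ("pre", "post"):
        if scan not in wide.columns:
            raise ValueError(f"no '{scan}' strengths in the table")
    orphans = sorted(set(subjects["subject_id"]) ^ set(wide.index))
    if orphans:
        raise ValueError(f"subjects without matching strengths (or vice versa): "
                         f"{orphans[:10]}")
    missing = wide[["pre", "post"]].isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"missing scan for subjects {wide.index[missing].tolist()[:10]}"
        )
    # the strength table is authoritative for strengths; drop any copies the
    # subject table happens to carry so the merge cannot collide
    subjects = subjects.drop(columns=["strength_pre", "strength_post"],
                             errors="ignore")
    merged = subjects.merge(
        wide[["pre", "post"]].rename(
            columns={"pre": "strength_pre", "post": "strength_post"}
        ),
        left_on="subject_id", right_index=True, validate="1:1",
    )
    return CohortTable(subjects=merged), strengths


def strengths_from_timeseries(
    timeseries_dir: str | Path,
    atlas: NetworkAtlas,
    network: str = "DMN",
    split_half: bool = False,
) -> pd.DataFrame:
    """Compute a long-format strength table from ``<subject>_<scan>.tsv``
    files (scan in {pre, post}), optionally adding split-half strengths."""
    ts_dir = Path(timeseries_dir)
    rows = []
    files = sorted(ts_dir.glob("*_*.tsv"))
    if not files:
        raise FileNotFoundError(f"no '<subject>_<scan>.tsv' files in {ts_dir}")
    for f in files:
        subject, scan = f.stem.rsplit("_", 1)
        if scan not in ("pre", "post"):
            continue
        ts = read_timeseries(f, scan_label=scan)
        sv = scan_strength(ts, atlas, network)
        rows.append({"subject": subject, "scan_label": scan, "network": network,
                     "n_nodes": sv.n_nodes, "value": sv.value})
        if split_half:
            for half in split_halves(ts):
                hv = scan_strength(half, atlas, network)
                rows.append({"subject": subject, "scan_label": half.scan_label,
                             "network": network, "n_nodes": hv.n_nodes,
                             "value": hv.value})
    return pd.DataFrame(rows)


def nodal_exploration(
    matrices: dict[str, ConnectivityMatrix],
    atlas: NetworkAtlas,
    subjects: pd.DataFrame,
    network: str = "DMN",
    fdr: bool = True,
) -> pd.DataFrame:
    """Per-node group contrast of nodal strength (independent pooled t).

    ``matrices`` maps subject_id -> Fisher-z matrix for the chosen condition.
    Returns one row per network member node with the signed PTSD-minus-MDD
    effect, raw p, and FDR-adjusted p, sorted by |effect| descending.
    """
    members = atlas.members(network)
    if len(members) < 2:
        raise ValueError(f"network {network!r} needs >=2 member nodes")
    groups = dict(zip(subjects["subject_id"], subjects["group"]))
    missing = sorted(set(groups) - set(matrices))
    if missing:
        raise ValueError(f"missing matrices for subjects {missing[:10]}")
    per_subject = {
        sid: nodal_strength(matrices[sid], atlas, network) for sid in groups
    }
    rows = []
    for i, node in enumerate(members):
        vals = {g: [] for g in ("PTSD", "MDD")}
        for sid, g in groups.items():
            vals[g].append(per_subject[sid].values[i])
        x, y = np.asarray(vals["PTSD"]), np.asarray(vals["MDD"])
        from .inference import _pooled_t
        from scipy import stats

        t, se, df = _pooled_t(x, y)
        rows.append({"node": node, "effect": float(x.mean() - y.mean()),
                     "t": float(t), "df": df,
                     "p": float(2.0 * stats.t.sf(abs(t), df))})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = fdr_adjust(table["p"], method="bh" if fdr else "bonferroni")
    table = table.reindex(
        table["effect"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return table


def _half_cohort(cohort: CohortTable, strengths: pd.DataFrame, run: str,
                 network: str) -> Optional[CohortTable]:
    labels = {f"{run}_h1", f"{run}_h2"}
    if not labels.issubset(set(strengths["scan_label"])):
        return None
    wide = strengths[strengths["scan_label"].isin(labels)].pivot_table(
        index="subject", columns="scan_label", values="value", aggfunc="first"
    )
    df = cohort.subjects[["subject_id", "group"]].merge(
        wide.rename(columns={f"{run}_h1": "strength_pre",
                             f"{run}_h2": "strength_post"}),
        left_on="subject_id", right_index=True, validate="1:1",
    )
    return CohortTable(subjects=df)


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Run the full battery on one cohort and (optionally) write the report."""
    log.info("percent-difference denominators: pre-stress group mean for "
             "stress effects, MDD mean (same condition) for group effects")
    log.info("stress main effect uses unweighted group means")
    log.info("FDR method: %s", "Benjamini-Hochberg" if cfg.fdr else "Bonferroni")

    matrices: Optional[dict[str, ConnectivityMatrix]] = None
    if cfg.timeseries_dir is not None:
        atlas = read_atlas(cfg.atlas_path)
        strengths = strengths_from_timeseries(
            cfg.timeseries_dir, atlas, cfg.network, split_half=cfg.split_half
        )
        strengths_path = None
        if cfg.out_dir is not None:
            out = Path(cfg.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            strengths_path = out / "strengths.csv"
            strengths.to_csv(strengths_path, index=False)
        import tempfile

        if cfg.subjects_csv is None:
            raise ValueError("subjects_csv is required")
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            strengths.to_csv(fh, index=False)
            tmp = fh.name
        cohort, strengths = load_cohort(cfg.subjects_csv, tmp, cfg.network)
        Path(tmp).unlink()
        if cfg.nodal:
            matrices = {}
            for f in sorted(Path(cfg.timeseries_dir).glob("*_*.tsv")):
                subject, scan = f.stem.rsplit("_", 1)
                if scan != cfg.nodal_condition:
                    continue
                ts = read_timeseries(f, scan_label=scan)
                matrices[subject] = fisher_z(correlation_matrix(ts))
    else:
        if cfg.subjects_csv is None:
            raise ValueError("subjects_csv is required")
        cohort, strengths = load_cohort(cfg.subjects_csv, cfg.strengths_csv,
                                        cfg.network)

    anova = mixed_anova_2x2(cohort)

    simple = {}
    for group in ("PTSD", "MDD"):
        contrast = simple_effect(cohort, group)
        pre_mean = cohort.group_values(group, "strength_pre").mean()
        simple[group] = {
            "contrast": contrast,
            "percent": percent_difference(contrast.mean_difference, pre_mean),
        }

    contrasts = {}
    for condition in ("pre", "post", "mean"):
        contrast = group_contrast(cohort, condition)
        col = {"pre": "strength_pre", "post": "strength_post"}.get(condition)
        if col is None:
            mdd_ref = cohort.group_values("MDD", "strength_pre").mean() / 2 + \
                cohort.group_values("MDD", "strength_post").mean() / 2
        else:
            mdd_ref = cohort.group_values("MDD", col).mean()
        contrasts[condition] = {
            "contrast": contrast,
            "percent": percent_difference(contrast.mean_difference, mdd_ref),
        }

    ancova = None
    if cfg.covariates:
        ancova = ancova_interaction(cohort, list(cfg.covariates))

    severity = {}
    for score, group in SEVERITY_SCORES:
        if score not in cohort.subjects.columns:
            continue
        sub = cohort.subjects[cohort.subjects["group"] == group]
        vals = pd.to_numeric(sub[score], errors="coerce")
        ok = vals.notna()
        if ok.sum() < 4:
            continue
        delta = (sub["strength_post"] - sub["strength_pre"])[ok]
        res = correlation_test(delta.to_numpy(float), vals[ok].to_numpy(float))
        severity[f"{score}_{group}"] = {"r": res.r, "n": res.n, "p": res.p}

    duration: dict[str, dict[str, AnovaResult]] = {}
    if cfg.split_half:
        for run in ("pre", "post"):
            half = _half_cohort(cohort, strengths, run, cfg.network)
            if half is not None:
                duration[run] = duration_analysis(half)

    nodal = None
    if matrices is not None:
        nodal = nodal_exploration(matrices, atlas, cohort.subjects,
                                  cfg.network, fdr=cfg.fdr)

    echo = dataclasses.asdict(cfg)
    echo.pop("out_dir", None)  # output location must not affect report bytes
    report = AnalysisReport(
        anova=anova,
        simple_effects=simple,
        group_contrasts=contrasts,
        ancova=ancova,
        severity_correlations=severity,
        duration=duration,
        nodal=nodal,
        provenance={"config": echo, "version": __version__, "seed": cfg.seed,
                    "alpha": cfg.alpha, "network": cfg.network,
                    "conventions": {
                        "stress_main_effect": "unweighted group means",
                        "percent_reference_stress": "group pre-stress mean",
                        "percent_reference_group": "MDD mean, same condition",
                        "fdr": "benjamini-hochberg" if cfg.fdr else "bonferroni",
                    }},
    )
    if cfg.out_dir is not None:
        report.write(cfg.out_dir)
    return report
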