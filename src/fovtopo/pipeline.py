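"""Configuration-driven end-to-end cohort analysis.

``run`` wires the stages together in acquisition order: synthesize (or load)
a cohort of segmented scans, locate each scan's fovea (difference-of-
Gaussians fit of total retinal thickness in controls, averaged observer
marks in albinism), recenter and grid the thickness profiles, average the
two repeat segmentations, compute per-quadrant AUC and asymmetry ratios,
then run the group statistics: repeatability (Bland-Altman on the repeat
grids), interocular symmetry (paired t), random eye selection, and the
normality-gated control-vs-albinism comparisons, plus demographics.

Every scan appears exactly once in the inclusion log, either included or
excluded with one of the enumerated reasons (LOW_CONTRAST, NOT_FOVEAL,
SHORT_COVERAGE, NO_FRAMES_PASS_NCC).  All randomness flows from the single
configured seed, so reruns are bit-identical.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .fovea import eccentricity_axis, fit_dog_center, observer_center
from .layers import thickness_profiles
from .phantom import CohortData, CohortRanges, ScanGrid, make_cohort
from .stats import (
    bland_altman,
    chi_square_2x2,
    compare_groups,
    paired_t,
    select_random_eye,
)
from .topo import (
    CoverageError,
    MissingQuadrantError,
    asymmetry_ratio,
    average_repeats,
    gcl_fraction,
    interpolate_grid,
    quadrant_auc,
    summed_auc,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "ConfigError",
    "EXCLUSION_CODES",
    "run",
    "analyze_cohort",
    "demographics_summary",
    "load_study_demographics",
]

EXCLUSION_CODES = ("LOW_CONTRAST", "NOT_FOVEAL", "SHORT_COVERAGE", "NO_FRAMES_PASS_NCC")

METRIC_LAYERS = ("GCL", "IPL", "GCIPL")


class ConfigError(ValueError):
    """Configuration failed validation; nothing was computed."""


@dataclass
class RunConfig:
    """All knobs of one end-to-end run.  ``seed`` is mandatory."""

    seed: int
    n_control: int = 25
    n_albinism: int = 30
    ranges: CohortRanges | None = None
    grid: ScanGrid | None = None
    step_mm: float = 0.1
    halfwidth_mm: float = 2.5
    ncc_threshold: float = 0.85
    max_frames: int = 30
    strip_width_px: int = 64

    def validate(self) -> None:
        problems = []
        if not isinstance(self.seed, (int, np.integer)):
            problems.append("seed: must be an integer")
        if self.n_control < 1:
            problems.append("n_control: must be >= 1")
        if self.n_albinism < 1:
            problems.append("n_albinism: must be >= 1")
        if not 0 < self.ncc_threshold <= 1:
            problems.append("ncc_threshold: must be in (0, 1]")
        if self.max_frames < 1:
            problems.append("max_frames: must be >= 1")
        if self.strip_width_px < 1:
            problems.append("strip_width_px: must be >= 1")
        if self.step_mm <= 0:
            problems.append("step_mm: must be > 0")
        if self.halfwidth_mm <= 0:
            problems.append("halfwidth_mm: must be > 0")
        elif abs(round(self.halfwidth_mm / self.step_mm) * self.step_mm
                 - self.halfwidth_mm) > 1e-9:
            problems.append("halfwidth_mm: must be an integer multiple of step_mm")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {', '.join(sorted(unknown))}")
        if "ranges" in d and isinstance(d["ranges"], dict):
            d = dict(d)
            d["ranges"] = CohortRanges(**{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in d["ranges"].items()})
        if "grid" in d and isinstance(d["grid"], dict):
            d = dict(d)
            d["grid"] = ScanGrid(**d["grid"])
        return cls(**d)


@dataclass
class RunResult:
    """Everything one run produces, in memory."""

    cohort: pd.DataFrame
    metrics: pd.DataFrame
    fractions: pd.DataFrame
    stats_report: dict
    bland_altman: dict
    demographics: dict
    inclusion_log: list

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(out / "cohort.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.fractions.to_csv(out / "fractions.csv", index=False)
        fio.write_json(self.stats_report, out / "stats.json")
        fio.write_json(
            {k: vars(v) for k, v in self.bland_altman.items()},
            out / "bland_altman.json",
        )
        fio.write_json(self.demographics, out / "demographics.json")
        fio.write_json(self.inclusion_log, out / "inclusion_log.json")


def _scan_quadrants(record, group, config):
    """Process one scan: center, recenter, grid, average repeats.

    Returns (per-layer dict of averaged gridded profiles, repeat pair of
    gridded GCL thickness arrays, center) or raises CoverageError.
    """
    prof1 = thickness_profiles(record.contours_rep1)
    prof2 = thickness_profiles(record.contours_rep2)
    if group == "albinism":
        center = observer_center(record.observer_marks_mm)
    else:
        trt_mean = prof1["TRT"]
        trt_mean = type(trt_mean)(
            ecc_mm=trt_mean.ecc_mm,
            thickness_um=0.5 * (prof1["TRT"].thickness_um + prof2["TRT"].thickness_um),
            layer="TRT",
            meta=trt_mean.meta,
        )
        center = fit_dog_center(trt_mean)
    averaged = {}
    gcl_pair = None
    for layer in METRIC_LAYERS:
        g1 = interpolate_grid(
            eccentricity_axis(prof1[layer], center),
            config.step_mm, config.halfwidth_mm,
        )
        g2 = interpolate_grid(
            eccentricity_axis(prof2[layer], center),
            config.step_mm, config.halfwidth_mm,
        )
        averaged[layer] = average_repeats(g1, g2)
        if layer == "GCL":
            gcl_pair = (g1.thickness_um.copy(), g2.thickness_um.copy())
    return averaged, gcl_pair, center


def analyze_cohort(cohort: CohortData, config: RunConfig) -> RunResult:
    """Run the full metrics + statistics battery on an in-memory cohort."""
    config.validate()
    group_of = dict(zip(cohort.table["participant"], cohort.table["group"]))
    inclusion_log: list = []
    per_scan: dict = {}  # (pid, eye, orientation) -> dict of layer aucs etc.
    ba_pairs: dict = {}  # (group, orientation) -> [firsts, seconds]
    frac_rows = []

    for key in cohort.scans:
        pid, eye, orientation = key
        record = cohort.scans[key]
        group = group_of[pid]
        if not record.contours_rep1.meta.foveal:
            inclusion_log.append(
                {"scan": key, "included": False, "reason": "NOT_FOVEAL"}
            )
            continue
        try:
            averaged, gcl_pair, center = _scan_quadrants(record, group, config)
        except CoverageError as e:
            inclusion_log.append(
                {"scan": key, "included": False, "reason": "SHORT_COVERAGE",
                 "detail": str(e)}
            )
            continue
        neg, pos = averaged["GCL"].neg_label, averaged["GCL"].pos_label
        aucs = {
            layer: {
                neg: quadrant_auc(averaged[layer], neg),
                pos: quadrant_auc(averaged[layer], pos),
            }
            for layer in METRIC_LAYERS
        }
        per_scan[key] = {"aucs": aucs, "center": center}
        ba_pairs.setdefault((group, orientation), [[], []])
        ba_pairs[(group, orientation)][0].append(gcl_pair[0])
        ba_pairs[(group, orientation)][1].append(gcl_pair[1])
        frac = gcl_fraction(averaged["GCL"], averaged["GCIPL"])
        row = {"participant": pid, "group": group, "eye": eye,
               "orientation": orientation}
        for x, f in zip(averaged["GCL"].ecc_mm, frac):
            row[f"frac_{x:+.1f}mm"] = f
        frac_rows.append(row)
        inclusion_log.append({"scan": key, "included": True,
                              "center_mm": center.abscissa_mm,
                              "center_method": center.method})

    # --- per participant-eye metrics -------------------------------------
    metric_rows = []
    eyes_seen: dict = {}
    for (pid, eye, _ori) in per_scan:
        eyes_seen.setdefault(pid, set()).add(eye)
    for pid in sorted(eyes_seen):
        for eye in sorted(eyes_seen[pid]):
            h = per_scan.get((pid, eye, "horizontal"))
            v = per_scan.get((pid, eye, "vertical"))
            for layer in METRIC_LAYERS:
                row = {
                    "participant": pid,
                    "group": group_of[pid],
                    "eye": eye,
                    "layer": layer,
                    "auc_T": np.nan, "auc_N": np.nan,
                    "auc_I": np.nan, "auc_S": np.nan,
                    "auc_sum": np.nan, "ratio_NT": np.nan, "ratio_SI": np.nan,
                }
                if h is not None:
                    a = h["aucs"][layer]
                    row["auc_T"], row["auc_N"] = a["temporal"], a["nasal"]
                    row["ratio_NT"] = asymmetry_ratio(a["nasal"], a["temporal"])
                if v is not None:
                    a = v["aucs"][layer]
                    row["auc_I"], row["auc_S"] = a["inferior"], a["superior"]
                    row["ratio_SI"] = asymmetry_ratio(a["superior"], a["inferior"])
                try:
                    row["auc_sum"] = summed_auc(
                        {"temporal": row["auc_T"], "nasal": row["auc_N"],
                         "inferior": row["auc_I"], "superior": row["auc_S"]}
                    )
                except MissingQuadrantError:
                    pass  # reported as missing (NaN), never imputed
                metric_rows.append(row)
    metrics = pd.DataFrame(metric_rows)

    # --- repeatability ----------------------------------------------------
    ba = {}
    for (group, orientation), (firsts, seconds) in sorted(ba_pairs.items()):
        ba[f"{group}_{orientation}"] = bland_altman(
            np.concatenate(firsts), np.concatenate(seconds)
        )

    # --- interocular symmetry (both-eye participants) ---------------------
    stats_report: dict = {"interocular": {}, "group_comparison": {}}
    if not metrics.empty:
        for layer in METRIC_LAYERS:
            sub = metrics[metrics["layer"] == layer]
            for metric in ("auc_sum", "ratio_NT", "ratio_SI"):
                wide = sub.pivot_table(
                    index="participant", columns="eye", values=metric
                ).dropna()
                if {"OD", "OS"}.issubset(wide.columns) and len(wide) >= 2:
                    t, df, p = paired_t(wide["OD"].to_numpy(), wide["OS"].to_numpy())
                    stats_report["interocular"][f"{layer}_{metric}"] = {
                        "t": t, "df": df, "p": p, "n_pairs": int(len(wide)),
                    }

    # --- random eye selection + group comparisons -------------------------
    selection = select_random_eye(
        {pid: sorted(eyes) for pid, eyes in eyes_seen.items()}, seed=config.seed
    )
    stats_report["eye_selection"] = selection
    if not metrics.empty:
        sel_mask = metrics.apply(
            lambda r: selection.get(r["participant"]) == r["eye"], axis=1
        )
        selected = metrics[sel_mask]
        for layer in METRIC_LAYERS:
            sub = selected[selected["layer"] == layer]
            for metric in ("auc_sum", "ratio_NT", "ratio_SI"):
                a = sub.loc[sub["group"] == "control", metric].dropna().to_numpy()
                b = sub.loc[sub["group"] == "albinism", metric].dropna().to_numpy()
                if a.size >= 2 and b.size >= 2:
                    cmp_ = compare_groups(a, b)
                    stats_report["group_comparison"][f"{layer}_{metric}"] = {
                        **cmp_.to_dict(),
                        "control_mean": float(a.mean()),
                        "control_sd": float(a.std(ddof=1)),
                        "albinism_mean": float(b.mean()),
                        "albinism_sd": float(b.std(ddof=1)),
                        "n_control": int(a.size),
                        "n_albinism": int(b.size),
                    }

    demographics = demographics_summary(cohort.table)
    return RunResult(
        cohort=cohort.table,
        metrics=metrics,
        fractions=pd.DataFrame(frac_rows),
        stats_report=stats_report,
        bland_altman=ba,
        demographics=demographics,
        inclusion_log=inclusion_log,
    )


def run(config: RunConfig, outdir=None) -> RunResult:
    """Simulate a cohort under ``config`` and analyze it end to end."""
    config.validate()
    cohort = make_cohort(
        n_control=config.n_control,
        n_albinism=config.n_albinism,
        ranges=config.ranges,
        seed=config.seed,
        grid=config.grid,
    )
    result = analyze_cohort(cohort, config)
    if outdir is not None:
        result.write(outdir)
    return result


# ---------------------------------------------------------------------------
# demographics


def _eye_mean_al(row) -> float:
    vals = [v for v in (row.get("al_od_mm"), row.get("al_os_mm")) if pd.notna(v)]
    return float(np.mean(vals)) if vals else np.nan


def demographics_summary(table: pd.DataFrame) -> dict:
    """Group demographics (mean ± SD age, % female, axial length) and the
    between-group tests: gated comparison for age and axial length,
    Yates chi-square for sex."""
    groups = list(dict.fromkeys(table["group"]))
    if not groups:
        raise ValueError("empty cohort table")
    out: dict = {"groups": {}}
    per_group = {}
    for g in groups:
        sub = table[table["group"] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} is empty")
        ages = sub["age_years"].to_numpy(dtype=float)
        al = sub.apply(_eye_mean_al, axis=1).to_numpy(dtype=float)
        al = al[np.isfinite(al)]
        n_f = int((sub["sex"] == "F").sum())
        out["groups"][g] = {
            "n": int(len(sub)),
            "age_mean": float(ages.mean()),
            "age_sd": float(ages.std(ddof=1)) if len(ages) > 1 else 0.0,
            "pct_female": 100.0 * n_f / len(sub),
            "al_mean": float(al.mean()) if al.size else np.nan,
            "al_sd": float(al.std(ddof=1)) if al.size > 1 else np.nan,
        }
        per_group[g] = {"ages": ages, "al": al,
                        "sex": (n_f, int(len(sub)) - n_f)}
    if len(groups) == 2:
        a, b = groups
        out["age_test"] = compare_groups(per_group[a]["ages"], per_group[b]["ages"]).to_dict()
        out["al_test"] = compare_groups(per_group[a]["al"], per_group[b]["al"]).to_dict()
        chi2, p = chi_square_2x2([per_group[a]["sex"], per_group[b]["sex"]])
        out["sex_test"] = {"chi2": chi2, "p": p}
    return out


def load_study_demographics() -> pd.DataFrame:
    """The study's published participant tables, as one DataFrame.

    Controls and albinism participants included in the final analysis, with
    per-eye axial lengths (one albinism left eye was not measured).
    """
    base = importlib.resources.files("fovtopo") / "data"
    ctrl = pd.read_csv(str(base / "table1_controls.csv"))
    ctrl["group"] = "control"
    alb = pd.read_csv(str(base / "table2_albinism.csv"))
    alb["group"] = "albinism"
    return pd.concat([ctrl, alb], ignore_index=True)
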