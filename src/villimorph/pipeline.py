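"""End-to-end orchestration: simulate → measure → analyze → report.

A run reproduces the shape of a full trial analysis from a single master
seed: synthetic biopsy images with ground truth, the morphometry table
measured from those images, a masked simulated cohort, a CONSORT-style
attrition table, routed statistical comparisons after database lock and
unblinding, and a textual results report.  Identical config + seed give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortsim, morphometry, stats, synthhist

__all__ = ["RunConfig", "run_pipeline", "render_report", "measure_images"]

log = logging.getLogger("villimorph")

RESULT_COLUMNS = [
    "variable", "stratum", "test", "estimate", "ci_low", "ci_high",
    "statistic", "p", "n_mm", "n_placebo",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML round-trippable).

    Every random stage derives its seed deterministically from
    ``master_seed``.  Stage toggles allow partial runs; morphometry and
    statistics options are passed through to the respective modules.
    """

    master_seed: int = 0
    simulate_images: bool = True
    measure: bool = True
    simulate_cohort: bool = True
    analyze: bool = True
    report: bool = True
    n_images: int = 3
    image_noise_sd: float = 5.0
    um_per_pixel: float = 1.0
    tilt_tolerance_deg: float = 30.0
    cd_rule: str = "mean"
    welch: bool = False
    holm: bool = False
    scenario: str = "paper"  # "paper" | "null"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = sum(ord(c) * 31**i for i, c in enumerate(stage)) % (2**31)
    ss = np.random.SeedSequence([master_seed, digest])
    return int(ss.generate_state(1)[0] % (2**31))


def _image_specs(config: RunConfig, seed: int) -> list[synthhist.MucosaSpec]:
    """Biopsy-like image specs spanning blunted to preserved villi."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(config.n_images):
        vh = float(rng.uniform(180, 380))
        vw = float(rng.uniform(80, 130))
        specs.append(
            synthhist.MucosaSpec(
                n_villi=int(rng.integers(2, 5)),
                villus_height_um=round(vh, 1),
                villus_width_um=round(vw, 1),
                crypt_depth_um=round(float(rng.uniform(120, 200)), 1),
                muscularis_length_um=round(float(rng.uniform(600, 900)), 1),
                um_per_pixel=config.um_per_pixel,
                noise_sd=config.image_noise_sd,
                seed=int(rng.integers(0, 2**31)),
            )
        )
    return specs


def measure_images(image_dir: str | Path, **morph_kwargs) -> pd.DataFrame:
    """Measure every image (with JSON sidecar) in a directory."""
    image_dir = Path(image_dir)
    rows = []
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    for path in paths:
        image = synthhist.load_image(path)
        annotation = synthhist.load_annotation(path.with_suffix(".json"))
        rec = morphometry.summarize_biopsy(image, annotation, **morph_kwargs)
        rows.append({"biopsy_id": path.stem, **rec.to_dict()})
    cols = [
        "biopsy_id", "VH", "CD", "VW", "VP_per100", "VA_per100",
        "muscularis_length_um", "adequate",
    ]
    return pd.DataFrame(rows, columns=cols)


def _consort_table(data: pd.DataFrame) -> pd.DataFrame:
    """Randomised vs analyzable participant counts per (unblinded) arm."""
    pre = data[data["timepoint"] == "pre"]
    rows = []
    for arm, grp in pre.groupby("arm"):
        rows.append(
            {
                "arm": arm,
                "randomised": len(grp),
                "analyzable": int(grp["adequate"].sum()),
                "excluded_orientation": int((~grp["adequate"]).sum()),
            }
        )
    return pd.DataFrame(rows).sort_values("arm").reset_index(drop=True)


def _results_frame(results: list[stats.ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.ci95 if r.ci95 is not None else (float("nan"), float("nan"))
        rows.append(
            {
                "variable": r.variable,
                "stratum": r.stratum,
                "test": r.test_name,
                "estimate": round(r.estimate, 4),
                "ci_low": round(lo, 4),
                "ci_high": round(hi, 4),
                "statistic": round(r.statistic, 4),
                "p": float(f"{r.p_value:.6g}"),
                "n_mm": r.n_per_group[0],
                "n_placebo": r.n_per_group[1],
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _format_p(p: float) -> str:
    """Printed-precision p-values: 1 s.f. below 0.01, else 2 d.p."""
    if np.isnan(p):
        return "P undefined"
    if p < 0.001:
        return f"P = {p:.1g}"
    if p < 0.01:
        return f"P = {p:.3f}"
    return f"P = {p:.2f}"


def render_report(
    results: pd.DataFrame, group_means: pd.DataFrame | None = None
) -> str:
    """Markdown report: one sentence per stratum/variable comparison.

    ``group_means`` (optional) carries per-(stratum, variable, arm) group
    centres so percent differences can be quoted alongside the estimate.
    """
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    if results.empty:
        return "# Morphometry results\n\nNo comparisons were produced.\n"
    lines = ["# Morphometry results", ""]
    for stratum, grp in results.groupby("stratum", sort=True):
        lines.append(f"## HIV {stratum} participants")
        lines.append("")
        for _, row in grp.iterrows():
            centre_kind = "mean" if "t test" in row["test"] else "median"
            sentence = (
                f"{row['variable']}: {centre_kind} difference "
                f"{row['estimate']:.1f}"
            )
            if np.isfinite(row["ci_low"]):
                sentence += f" [95% CI {row['ci_low']:.1f} – {row['ci_high']:.1f}]"
            if group_means is not None:
                sel = group_means[
                    (group_means["stratum"] == stratum)
                    & (group_means["variable"] == row["variable"])
                ]
                if len(sel) == 2:
                    mm = float(sel.loc[sel["arm"] == "MM", "centre"].iloc[0])
                    pl = float(sel.loc[sel["arm"] == "placebo", "centre"].iloc[0])
                    if pl != 0:
                        pct = stats.percent_difference(mm, pl)
                        sentence += (
                            f"; {centre_kind} {pct:+.1f}% with MM "
                            f"({mm:.1f} v. {pl:.1f})"
                        )
            sentence += f"; {_format_p(row['p'])}, {row['test']}."
            lines.append(f"- {sentence}")
        lines.append("")
    return "\n".join(lines)


def _group_means(data: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Group centres (mean or median to match each comparison's route)."""
    pre = data[(data["timepoint"] == "pre") & data["adequate"]]
    rows = []
    for _, r in results.iterrows():
        sub = pre[pre["hiv"] == r["stratum"]]
        use_mean = "t test" in r["test"]
        for arm, grp in sub.groupby("arm"):
            vals = grp[r["variable"]].dropna()
            centre = float(vals.mean() if use_mean else vals.median())
            rows.append(
                {
                    "stratum": r["stratum"],
                    "variable": r["variable"],
                    "arm": arm,
                    "centre": centre,
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "variable", "arm", "centre"])


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the configured stages into ``out_dir``; returns the path.

    Output layout (all plain text or PNG):
    ``images/`` (PNG + JSON sidecars + manifest), ``morphometry.csv``,
    ``cohort.csv`` + ``codemap.json``, ``consort.csv``, ``results.csv``,
    ``report.md``, ``run.log`` (every seed, threshold and exclusion),
    and the resolved ``config.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"master_seed={config.master_seed}"]
    config.to_yaml(out_dir / "config.yaml")

    stages_on = any(
        (config.simulate_images, config.measure, config.simulate_cohort,
         config.analyze, config.report)
    )
    if not stages_on:
        log.warning("all stages disabled; run directory %s left empty", out_dir)
        (out_dir / "run.log").write_text("all stages disabled\n")
        return out_dir

    if config.simulate_images:
        seed = _stage_seed(config.master_seed, "images")
        log_lines.append(f"stage images: seed={seed}, n={config.n_images}")
        specs = _image_specs(config, seed)
        synthhist.render_batch(specs, out_dir / "images")

    if config.measure:
        if not (out_dir / "images").exists():
            raise RuntimeError("stage 'measure' failed: no images directory; "
                               "enable simulate_images or provide images/")
        table = measure_images(
            out_dir / "images",
            tilt_tolerance_deg=config.tilt_tolerance_deg,
            cd_rule=config.cd_rule,
        )
        table.to_csv(out_dir / "morphometry.csv", index=False)
        log_lines.append(
            f"stage measure: {len(table)} biopsies, "
            f"{int(table['adequate'].sum())} adequate"
        )

    cohort = None
    if config.simulate_cohort:
        seed = _stage_seed(config.master_seed, "cohort")
        log_lines.append(f"stage cohort: seed={seed}, scenario={config.scenario}")
        if config.scenario == "paper":
            spec = cohortsim.paper_scenario(seed)
        elif config.scenario == "null":
            spec = cohortsim.null_scenario(seed)
        else:
            raise RuntimeError(
                f"stage 'cohort' failed: unknown scenario {config.scenario!r}"
            )
        cohort = cohortsim.simulate_cohort(spec)
        cohort.data.to_csv(out_dir / "cohort.csv", index=False)
        cohort.code_map.to_json(out_dir / "codemap.json")

    if config.analyze:
        if cohort is None:
            raise RuntimeError(
                "stage 'analyze' failed: no cohort (enable simulate_cohort)"
            )
        cohort.lock()
        unblinded = cohortsim.unblind(cohort)
        log_lines.extend(unblinded.audit)
        results = stats.route_and_compare(
            unblinded.data, welch=config.welch, holm=config.holm
        )
        frame = _results_frame(results)
        frame.to_csv(out_dir / "results.csv", index=False)
        consort = _consort_table(unblinded.data)
        consort.to_csv(out_dir / "consort.csv", index=False)
        for _, row in consort.iterrows():
            log_lines.append(
                f"consort: arm={row['arm']} randomised={row['randomised']} "
                f"analyzable={row['analyzable']}"
            )
        if config.report:
            means = _group_means(unblinded.data, frame)
            (out_dir / "report.md").write_text(render_report(frame, means))

    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return out_dir
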