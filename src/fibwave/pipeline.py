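"""Experiment-matrix orchestration and reporting.

Runs the full intervention matrix — genotype x {baseline, CPVI, CPVI+DFA,
three drugs x two doses} — over seeded synthetic substrates, one episode
per cell, and aggregates per-episode wave-dynamics rows into a results
table with defragmentation/termination rates and median [IQR] summaries.

High-DF-site ablation (DFA) is a conditional second pass: it is applied
only to episodes that were *not* defragmented by CPVI alone, using the
high-DF sites of the matching genotype's baseline DF map.  Baseline
episodes that fail to induce sustained AF are flagged and excluded from
intervention denominators.

Runs are resumable: each episode row is persisted as JSON in the output
directory and finished episodes are skipped on rerun.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry as geo
from . import protocols as pr
from . import tissue as ts
from . import wavedynamics as wd
from .presets import compose, drug_preset, genotype_baseline

log = logging.getLogger("fibwave.pipeline")

STANDARD_INTERVENTIONS = (
    pr.Intervention("none"),
    pr.Intervention("cpvi"),
    pr.Intervention("cpvi_dfa"),
    *(pr.Intervention("drug", drug=d, dose=do)
      for d in ("amiodarone", "dronedarone", "flecainide")
      for do in ("low", "high")),
)


@dataclass
class ExperimentConfig:
    """Full description of one experiment campaign."""

    seeds: tuple[int, ...] = tuple(range(1, 26))
    genotypes: tuple[str, ...] = pr.GENOTYPES
    interventions: tuple[pr.Intervention, ...] = STANDARD_INTERVENTIONS
    scale: str = "desk"                 # episode layout: "full" | "desk"
    dx: float = 0.75                    # lattice spacing of the substrates, mm
    dt: float = 0.1                     # tissue time step, ms
    target_cv: float = 0.6              # calibration target, m/s (longitudinal)
    geometry_kw: dict = field(default_factory=dict)
    smax_stride: int = 3                # node subsampling for Smax fitting
    outdir: str | None = None           # enables resumability when set

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("need at least one substrate seed")
        for iv in self.interventions:
            if iv.kind == "drug":
                drug_preset(iv.drug, iv.dose)  # resolvable now, not at run time

    def geometry(self, seed: int) -> geo.GeometryConfig:
        return geo.GeometryConfig(dx=self.dx, seed=seed, **self.geometry_kw)


COLUMNS = ["episode_id", "seed", "genotype", "intervention", "dose",
           "induced", "outcome", "defragmented", "mean_df_hz", "mean_smax",
           "afcl_ms", "parent", "status"]


def _episode_id(seed: int, genotype: str, iv: pr.Intervention) -> str:
    return f"s{seed}_{genotype}_{iv.label}"


def _run_one(grid, preset, plan, config, scale_factor):
    rec = ts.simulate(grid, preset, plan.schedule, plan.total_duration,
                      dt=config.dt, diffusion_scale=scale_factor)
    result = wd.analyze_episode(rec, plan.analysis_window,
                                smax_stride=config.smax_stride)
    sustained = _sustained(rec, plan)
    return rec, result, sustained


def _sustained(rec, plan) -> bool:
    """AF induction success: activity persisted to the episode end."""
    alive = [rec.activations(int(i))[-1] for i in np.flatnonzero(rec.n_act)]
    return bool(alive) and max(alive) >= plan.total_duration - wd.SILENCE_MS


def run_matrix(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Execute the full experiment matrix; returns the results table.

    For each substrate seed: build geometry, calibrate CV per genotype
    preset, run the baseline episode (keeping its DF map for DFA
    targeting), then every intervention.  Episode failures are recorded as
    rows with ``status='error'`` rather than dropped.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []

    for seed in config.seeds:
        grid0 = geo.make_geometry(config.geometry(seed))
        for genotype in config.genotypes:
            base_preset = genotype_baseline(genotype, "af")
            scale_factor = ts.calibrate_diffusion(
                grid0, base_preset, config.target_cv, dt=config.dt)
            plan = pr.episode_plan(genotype, "none", scale=config.scale)

            # ---- baseline (also provides the DF map for DFA and the
            # induction flag gating intervention denominators)
            base_row = _load_or_run(
                rows, outdir, seed, genotype, pr.Intervention("none"),
                lambda: _baseline_episode(grid0, base_preset, plan, config,
                                          scale_factor), progress)
            induced = bool(base_row["induced"])
            df_map_base = base_row.pop("_df_map", None)
            cpvi_outcome: str | None = None

            for iv in config.interventions:
                if iv.kind == "none":
                    continue

                def make():
                    return _intervention_episode(
                        grid0, base_preset, plan, config, scale_factor, iv,
                        genotype, df_map_base, cpvi_outcome, induced)

                row = _load_or_run(rows, outdir, seed, genotype, iv, make,
                                   progress)
                if iv.kind == "cpvi":
                    cpvi_outcome = row["outcome"]
    table = pd.DataFrame(rows, columns=COLUMNS)
    if table["episode_id"].duplicated().any():
        raise RuntimeError("duplicate episode keys")
    return table


def _baseline_episode(grid, preset, plan, config, scale_factor):
    rec, result, sustained = _run_one(grid, preset, plan, config, scale_factor)
    dfm = wd.df_map(rec, plan.analysis_window)
    row = dict(induced=sustained, outcome=result.outcome,
               defragmented=result.defragmented, mean_df_hz=result.mean_df,
               mean_smax=result.mean_smax, afcl_ms=result.afcl_ms,
               parent="", status="ok")
    row["_df_map"] = dfm.on_grid(grid.shape)
    return row


def _intervention_episode(grid, base_preset, plan, config, scale_factor, iv,
                          genotype, df_map_base, cpvi_outcome, induced):
    parent = ""
    if iv.kind == "drug":
        preset = compose(base_preset, drug_preset(iv.drug, iv.dose))
        g = grid
    else:
        preset = base_preset
        mask = pr.cpvi_mask(grid)
        if iv.kind == "cpvi_dfa":
            parent = _episode_id(int(grid.meta.get("seed", -1)), genotype,
                                 pr.Intervention("cpvi"))
            # conditional second pass: DFA only when CPVI alone failed
            if cpvi_outcome is not None and cpvi_outcome != "AF":
                return dict(induced=induced, outcome=cpvi_outcome,
                            defragmented=True, mean_df_hz=np.nan,
                            mean_smax=np.nan, afcl_ms=np.nan,
                            parent=parent, status="inherited_cpvi")
            if df_map_base is not None:
                dfa = pr.high_df_targets(df_map_base, ts.apply_ablation(grid, mask))
                mask = mask.union(dfa)
        g = ts.apply_ablation(grid, mask)
    rec, result, sustained = _run_one(g, preset, plan, config, scale_factor)
    return dict(induced=induced, outcome=result.outcome,
                defragmented=result.defragmented, mean_df_hz=result.mean_df,
                mean_smax=result.mean_smax, afcl_ms=result.afcl_ms,
                parent=parent, status="ok")


def _load_or_run(rows, outdir, seed, genotype, iv, builder, progress):
    eid = _episode_id(seed, genotype, iv)
    path = outdir / f"{eid}.json" if outdir else None
    if path is not None and path.exists():
        row = json.loads(path.read_text())
        dfm_path = path.with_suffix(".dfmap.npy")
        if dfm_path.exists():
            row["_df_map"] = np.load(dfm_path)
    else:
        try:
            row = builder()
        except Exception as exc:  # recorded, never silently dropped
            log.exception("episode %s failed", eid)
            row = dict(induced=False, outcome="AF", defragmented=False,
                       mean_df_hz=np.nan, mean_smax=np.nan, afcl_ms=np.nan,
                       parent="", status=f"error: {exc}")
        if path is not None:
            dfm = row.get("_df_map")
            if dfm is not None:
                np.save(path.with_suffix(".dfmap.npy"), dfm)
            path.write_text(json.dumps(
                {k: v for k, v in row.items() if not k.startswith("_")},
                default=_json_default))
    full = dict(episode_id=eid, seed=seed, genotype=genotype,
                intervention=iv.kind if iv.kind != "drug" else iv.drug,
                dose=iv.dose or "", **{k: v for k, v in row.items()
                                       if not k.startswith("_")})
    rows.append(full)
    if progress:
        print(f"[fibwave] {eid}: {full['outcome']} "
              f"(DF {full['mean_df_hz']})", flush=True)
    if "_df_map" in row:
        full["_df_map"] = row["_df_map"]
    return full


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(type(o))


def _rate(num: int, den: int) -> str:
    pct = 100.0 * num / den if den else np.nan
    return f"{pct:.1f}% ({num}/{den})"


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(genotype, intervention) summary: defragmentation and termination
    rates (with numerator/denominator) and median [IQR] wave-dynamics.

    Baseline rows where AF induction failed are excluded from intervention
    denominators; the induction-failure count is reported per group.
    """
    out = []
    for (gen, iv, dose), grp in table.groupby(
            ["genotype", "intervention", "dose"], sort=False, dropna=False):
        g = grp[grp["induced"].astype(bool)]
        n = len(g)
        defrag = int(g["defragmented"].sum())
        term = int((g["outcome"] == "terminated").sum())
        row = dict(genotype=gen, intervention=iv, dose=dose, n=n,
                   induction_failures=int((~grp["induced"].astype(bool)).sum()),
                   defragmentation=_rate(defrag, n),
                   termination=_rate(term, n),
                   defrag_pct=100.0 * defrag / n if n else np.nan,
                   term_pct=100.0 * term / n if n else np.nan)
        for col, name in (("mean_df_hz", "df_hz"), ("mean_smax", "smax"),
                          ("afcl_ms", "afcl_ms")):
            vals = g[col].dropna()
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row[name] = f"{med:.3g} [{q1:.3g}, {q3:.3g}]"
                row[f"{name}_median"] = med
            else:
                row[name] = "-"
                row[f"{name}_median"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def compare_groups(table: pd.DataFrame, by: str, groups: tuple[str, str],
                   metrics: tuple[str, ...] = ("mean_df_hz", "mean_smax",
                                               "afcl_ms")) -> pd.DataFrame:
    """Two-group comparison report.

    Continuous metrics: two-sided Mann-Whitney U (rank-sum).  Rates
    (defragmentation, termination): Fisher's exact test on the 2x2 counts.
    Reporting layer only — no multiplicity correction.
    """
    a = table[table[by] == groups[0]]
    b = table[table[by] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group in comparison {groups}")
    rows = []
    for m in metrics:
        x, y = a[m].dropna(), b[m].dropna()
        if len(x) and len(y):
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(dict(metric=m, test="mann-whitney", statistic=stat,
                             p_value=p))
        else:
            rows.append(dict(metric=m, test="mann-whitney",
                             statistic=np.nan, p_value=np.nan))
    for m, pred in (("defragmented", lambda g: g["defragmented"].astype(bool)),
                    ("terminated", lambda g: g["outcome"] == "terminated")):
        k1, n1 = int(pred(a).sum()), len(a)
        k2, n2 = int(pred(b).sum()), len(b)
        _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        rows.append(dict(metric=f"{m}_rate", test="fisher-exact",
                         statistic=np.nan, p_value=p))
    return pd.DataFrame(rows)
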