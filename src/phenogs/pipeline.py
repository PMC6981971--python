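"""End-to-end run over a fixture directory, driven by a YAML config.

Stages: read genotypes and plot-level trials; QC + impute markers; fit
combined BLUPs for yield and every index trait; build the
indirect-selection table; the top-fraction selection-overlap table per
index; and the cross-validated prediction-accuracy grid with and without
spectral covariates. Outputs are deterministic CSVs given identical
config + inputs.

Config keys: ``fixture_dir``, ``out_dir``, ``seed``, ``maf`` (default
0.05), ``cv_k`` (default 5), ``fixed_traits`` (default NDVI, NWI1, SR),
``selected_fraction`` (default 0.25).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import pandas as pd

from . import __version__
from .field_adjust import fit_adjusted_means
from .genomic_prediction import filter_maf, impute_missing, kfold_cv
from .io_formats import read_genotype_matrix, read_trial_table
from .quantgen import indirect_selection_report
from .selection_analysis import selection_overlap
from .sri import INDEX_NAMES

log = logging.getLogger("phenogs.pipeline")


def _write(path: Path, df: pd.DataFrame, cfg: dict) -> None:
    h = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# phenogs {__version__} seed={cfg.get('seed', 'NA')} config={h}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: dict) -> Path:
    fixture = Path(cfg["fixture_dir"])
    out = Path(cfg["out_dir"])
    if not fixture.is_dir():
        raise FileNotFoundError(f"fixture directory {fixture} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    maf = float(cfg.get("maf", 0.05))
    q = float(cfg.get("selected_fraction", 0.25))
    fixed_traits = cfg.get("fixed_traits", ["NDVI", "NWI1", "SR"])

    geno_path = fixture / "geno_DP.vcf"
    if not geno_path.exists():
        raise FileNotFoundError(f"missing genotype file {geno_path}")
    g = read_genotype_matrix(geno_path, "vcf")
    n0 = g.n_markers
    g = filter_maf(g, maf)
    log.info("MAF filter: %d -> %d markers", n0, g.n_markers)
    if g.missing.any():
        g = impute_missing(g, "mean")

    trials = {}
    pat = re.compile(r"trial_DP_(.+)\.csv")
    for f in sorted(fixture.glob("trial_DP_*.csv")):
        key = pat.match(f.name).group(1)
        trials[key] = read_trial_table(f, response=key)
    if "yield" not in trials:
        raise FileNotFoundError("fixture lacks a DP yield trial")

    # adjusted means (combined BLUPs) for every trait
    means = {}
    for key, trial in trials.items():
        means[key] = fit_adjusted_means(trial, "BLUP_combined").values
    means_df = pd.DataFrame(means).rename_axis("entry_id").reset_index()
    _write(out / "adjusted_means.csv", means_df, cfg)

    # indirect-selection table
    index_trials = {}
    for key, trial in trials.items():
        if key == "yield":
            continue
        name, stage = key.split("_", 1)
        if name in INDEX_NAMES:
            index_trials[(name, stage)] = trial
    if index_trials:
        table1 = indirect_selection_report(index_trials, trials["yield"])
        _write(out / "indirect_selection.csv", table1, cfg)

    # selection-overlap table
    rows = []
    for (name, stage), trial in sorted(index_trials.items()):
        crit = fit_adjusted_means(trial, "BLUP_combined").values
        rep = selection_overlap(means["yield"], crit, q=q, direction="auto",
                                criterion_name=f"{name}:{stage}")
        rows.append({"criterion": name, "stage": stage, "direction": rep.direction,
                     "overlap_percent": rep.overlap_percent,
                     "n_selected": rep.n_selected})
    if rows:
        _write(out / "selection_overlap.csv", pd.DataFrame(rows), cfg)

    # CV accuracy grid: no covariates, each fixed trait, all together
    y = means["yield"]
    y = y.loc[[li for li in y.index if li in set(g.line_ids)]]
    covs = {}
    for t in fixed_traits:
        cands = [k for k in means if k.startswith(f"{t}_")]
        if cands:
            covs[t] = means[cands[0]]
    cov_df = pd.DataFrame(covs)
    combos = [("none", None)]
    combos += [(t, cov_df[[t]]) for t in covs]
    if len(covs) > 1:
        combos.append(("+".join(covs), cov_df))
    acc_rows = []
    for label, fx in combos:
        res = kfold_cv(y, g, fx, k=int(cfg.get("cv_k", 5)), seed=seed)
        acc_rows.append({"fixed_effects": label, "accuracy": res.accuracy,
                         "n_lines": len(y)})
        log.info("CV [%s]: accuracy %.3f", label, res.accuracy)
    _write(out / "cv_accuracy.csv", pd.DataFrame(acc_rows), cfg)
    return out
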