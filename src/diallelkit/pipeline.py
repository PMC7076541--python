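"""End-to-end orchestration: QC -> ANOVA/effects -> components -> heterosis
-> GGE -> distances/Mantel, with one tidy CSV per result table.

Every stage output is a pure function of the input records and the run
configuration; the RNG seed is recorded in the run log and reused for the
Mantel permutations, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (DiallelDesign, entry_means, qc_normality, read_distance_csv,
                   read_phenotype_table, validate_design)
from .distances import DistanceMatrix, cross_statistic_to_matrix, euclidean_matrix, mantel
from .gge import build_entry_tester_matrix, center_by_tester, polygon_sectors, svd_biplot
from .griffing import (anova_combined, anova_single_env, griffing2_effects,
                       griffing4_effects, parents_vs_hybrids_contrast, rank_effects)
from .heterosis import heterosis_table
from .simulate import SimulationSpec, default_design, simulate_diallel
from .varcomp import components_combined, components_single_env

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one report run (see ``RunConfig.from_file``)."""

    phenotype: str | None = None  # CSV path; None -> simulate a demo trial
    genetic_distance: str | None = None  # symmetric labelled CSV, optional
    method: str = "method2"
    traits: list[str] = field(default_factory=list)  # empty -> all in data
    trait_directions: dict[str, str] = field(default_factory=dict)
    n_perm: int = 10_000
    seed: int = 0
    gge_f: float = 0.5
    outdir: str = "diallel_report"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat key: value (YAML) configuration file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _design_from_records(records: pd.DataFrame, method: str,
                         trait_directions: dict[str, str]) -> DiallelDesign:
    parents = list(pd.unique(pd.concat([records["parent_a"], records["parent_b"]])))
    envs = list(pd.unique(records["env"]))
    n_reps = int(records.groupby(["trait", "env", "parent_a", "parent_b"]).size().max())
    return DiallelDesign(parents=tuple(parents), method=method,  # type: ignore[arg-type]
                         n_reps=n_reps, environments=tuple(envs),
                         trait_directions=dict(trait_directions))  # type: ignore[arg-type]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns written paths."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def save(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written[name] = path

    if config.phenotype is None:
        design = default_design(method=config.method)
        spec = SimulationSpec(design=design, delta_self=-1.5, seed=config.seed)
        records, _ = simulate_diallel(spec)
    else:
        probe = DiallelDesign(parents=_peek_parents(config.phenotype),
                              method="method2", n_reps=1, environments=("_probe",))
        records = read_phenotype_table(config.phenotype, probe)
        design = _design_from_records(records, config.method, config.trait_directions)

    traits = config.traits or sorted(records["trait"].unique())
    balance = validate_design(records, design, traits=traits)
    has_selfs = not records[records["parent_a"] == records["parent_b"]].empty

    # --- QC -----------------------------------------------------------------
    qc_rows = []
    for trait in traits:
        for env in design.environments:
            sub = records[(records["trait"] == trait) & (records["env"] == env)]
            if len(sub) < 4:
                continue
            qc = qc_normality(records, trait, env)
            qc_rows.append({"trait": trait, "env": env, "n": qc.n, "mean": qc.mean,
                            "skewness": qc.skewness, "excess_kurtosis": qc.excess_kurtosis,
                            "zero_variance": qc.zero_variance})
    save("qc", pd.DataFrame(qc_rows))

    effects_fn = griffing2_effects if config.method == "method2" else griffing4_effects
    anova_frames, gca_rows, sca_rows, vc_rows, het_frames, gge_rows = [], [], [], [], [], []
    contrast_rows = []
    envs_with_data: dict[str, list[str]] = {}
    for trait in traits:
        direction = config.trait_directions.get(trait, design.direction(trait))
        envs = [e for e in design.environments
                if not records[(records["trait"] == trait) & (records["env"] == e)].empty]
        envs_with_data[trait] = envs
        for env in envs:
            anova = anova_single_env(records, trait, env, config.method, design)
            tab = anova.table.copy()
            tab.insert(0, "env", env)
            tab.insert(0, "trait", trait)
            anova_frames.append(tab)
            x = entry_means(
                records[records["parent_a"] != records["parent_b"]]
                if config.method == "method4" else records,
                trait, env, replace(design, method=config.method))
            eff = effects_fn(x, error_ms=anova.error_ms, n_reps=anova.n_reps)
            ranks = rank_effects(eff, direction)  # type: ignore[arg-type]
            for parent, gval in eff.g.items():
                gca_rows.append({"trait": trait, "env": env, "parent": parent,
                                 "gca": gval, "rank": int(ranks.g_rank[parent]),
                                 "se": eff.se_g})
            for (a, b), sval in ranks.s_rank.items():
                sca_rows.append({"trait": trait, "env": env, "parent_a": a, "parent_b": b,
                                 "sca": eff.s.loc[a, b], "rank": int(sval), "se": eff.se_s})
            vc = components_single_env(anova)
            row = {"trait": trait, "env": env, **vc.as_dict()}
            row.update({f"sig_{k}": v for k, v in vc.significance.items()})
            vc_rows.append(row)
            if has_selfs:
                het = heterosis_table(records, trait, env, design)
                htab = het.table.copy()
                htab.insert(0, "env", env)
                htab.insert(0, "trait", trait)
                het_frames.append(htab)
                con = parents_vs_hybrids_contrast(records, trait, env, design)
                contrast_rows.append({"trait": trait, "env": env,
                                      "estimate": con.estimate, "se": con.se,
                                      "t": con.t, "p": con.p, "df": con.df})
                xm2 = entry_means(records, trait, env, replace(design, method="method2"))
                model = svd_biplot(center_by_tester(build_entry_tester_matrix(xm2)),
                                   f=config.gge_f)
                poly = None if model.degenerate else polygon_sectors(model)
                for parent in design.parents:
                    gge_rows.append({
                        "trait": trait, "env": env, "genotype": parent,
                        "entry_pc1": model.entry_scores.loc[parent, "PC1"],
                        "entry_pc2": model.entry_scores.loc[parent, "PC2"],
                        "tester_pc1": model.tester_scores.loc[parent, "PC1"],
                        "tester_pc2": model.tester_scores.loc[parent, "PC2"],
                        "atc_abscissa": model.atc_abscissa[parent],
                        "atc_ordinate": model.atc_ordinate[parent],
                        "pc1_explained": model.explained[0] if len(model.explained) else np.nan,
                        "pc2_explained": model.explained[1] if len(model.explained) > 1 else np.nan,
                        "sector_winner": (poly.sector_of_tester[parent] if poly else ""),
                        "own_sector": (bool(poly.tester_in_own_sector[parent]) if poly else False),
                    })

        if len(envs) >= 2:
            comb = anova_combined(records, trait, config.method, design, environments=envs)
            tab = comb.table.copy()
            tab.insert(0, "env", "combined")
            tab.insert(0, "trait", trait)
            anova_frames.append(tab)
            vc = components_combined(comb)
            row = {"trait": trait, "env": "combined", **vc.as_dict()}
            row.update({f"sig_{k}": v for k, v in vc.significance.items()})
            vc_rows.append(row)

    save("anova", pd.concat(anova_frames, ignore_index=True))
    save("gca", pd.DataFrame(gca_rows))
    save("sca", pd.DataFrame(sca_rows))
    save("variance_components", pd.DataFrame(vc_rows))
    if het_frames:
        save("heterosis", pd.concat(het_frames, ignore_index=True))
        save("parents_vs_hybrids", pd.DataFrame(contrast_rows))
    if gge_rows:
        save("gge_coordinates", pd.DataFrame(gge_rows))

    # --- distances & Mantel -------------------------------------------------
    if config.genetic_distance is not None and has_selfs:
        gd = DistanceMatrix(values=read_distance_csv(config.genetic_distance), kind="genetic")
        order = [p for p in design.parents if p in gd.labels]
        gd = DistanceMatrix(values=gd.values.loc[order, order], kind="genetic")
        mantel_rows = []
        rng = np.random.default_rng(config.seed)
        for trait in traits:
            for env in envs_with_data[trait]:
                x = entry_means(records, trait, env, replace(design, method="method2"))
                profiles = pd.DataFrame({trait: x.diagonal()})
                lsm = cross_statistic_to_matrix(x.cross_series(), list(design.parents))
                het = heterosis_table(records, trait, env, design)
                ht = het.table.set_index(["parent_a", "parent_b"])
                comparisons = {
                    "LsM": lsm,
                    "MPH": cross_statistic_to_matrix(ht["MPH"], list(design.parents)),
                    "BPH": cross_statistic_to_matrix(ht["BPH"], list(design.parents)),
                }
                for name, mat in comparisons.items():
                    sel = DistanceMatrix(values=mat.values.loc[order, order],
                                         kind="cross_statistic")
                    res = mantel(gd, sel, n_perm=config.n_perm,
                                 seed=int(rng.integers(2**31 - 1)))
                    mantel_rows.append({"trait": trait, "env": env, "matrix": name,
                                        "r": res.r, "p": res.p_value,
                                        "n_perm": res.n_perm})
        save("mantel", pd.DataFrame(mantel_rows))

    log = {
        "diallelkit_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "method": config.method,
        "traits": traits,
        "balanced": balance.balanced,
        "n_records": int(len(records)),
        "elapsed_s": round(time.time() - t0, 3),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    written["run_log"] = log_path
    return written


def _peek_parents(path: str | Path) -> tuple[str, ...]:
    """Parent names in order of first appearance in a phenotype CSV."""
    head = pd.read_csv(path, usecols=["parent_a", "parent_b"])
    return tuple(pd.unique(pd.concat([head["parent_a"], head["parent_b"]]).astype(str)))
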