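"""End-to-end orchestration: simulate -> kinship -> prep -> h2 -> r_g atlas
-> cluster -> meta-traits -> scans -> report.

Each stage writes its artifacts under the run directory and records inputs,
outputs, parameters and output checksums in a JSON manifest; reruns with
unchanged inputs resume from completed stages.  Stage failures halt with the
stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import he_core, kinship as kin, rg_atlas, scan as scan_mod, simdata
from .config import RunConfig
from .pheno_prep import prepare_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {"stages": {}}

    def done(self, stage: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        for out, digest in rec["outputs"].items():
            p = Path(out)
            if not p.exists() or _checksum(p) != digest:
                return False
        return True

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "params": params,
            "outputs": {str(p): _checksum(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic-or-file pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    # ---- stage: simulate (or load) genotype substrate ------------------
    stage = "simulate"
    dosage_csv, map_csv, pheno_csv = out / "dosages.csv", out / "marker_map.csv", out / "phenotypes.csv"
    try:
        if not manifest.done(stage, [dosage_csv, map_csv, pheno_csv]):
            rng = np.random.default_rng(config.stage_seed(stage))
            spec = simdata.SimSpec(
                n_individuals=config.n_individuals, n_markers=config.n_markers,
                n_causal=config.n_causal, seed=config.stage_seed(stage),
            )
            G = simdata.simulate_genotypes(spec)
            covars = pd.DataFrame({
                "age": rng.integers(100, 800, size=G.n_individuals),
                "sex": rng.choice(["F", "M"], size=G.n_individuals),
                "generation": rng.choice(["G1", "G2"], size=G.n_individuals),
                "diet": rng.choice(["AL", "CR"], size=G.n_individuals),
            }, index=pd.Index(G.ids, name="id"))
            # a small block-structured trait panel so clustering has signal
            pheno = simdata.simulate_trait_blocks(
                G, n_blocks=2, traits_per_block=5, h2=0.5, rg_within=0.9,
                seed=config.stage_seed("traits"))
            simdata.write_genotypes_csv(G, dosage_csv, map_csv)
            simdata.write_phenotypes_csv(pheno, pheno_csv, covariates=covars)
            manifest.record(stage, {"n": config.n_individuals}, [dosage_csv, map_csv, pheno_csv])
        dosages = pd.read_csv(dosage_csv, index_col=0)
        marker_map = pd.read_csv(map_csv)
        table = pd.read_csv(pheno_csv, index_col=0)
        covar_cols = ["age", "sex", "generation", "diet"]
        covars = table[covar_cols]
        pheno = table.drop(columns=covar_cols)
        G = simdata.GenotypeMatrix(
            dosages.to_numpy(dtype=np.int8), dosages.to_numpy(dtype=float).mean(axis=0) / 2,
            marker_map, dosages.index.to_numpy(dtype=str),
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: kinship -------------------------------------------------
    stage = "kinship"
    kin_csv = out / "kinship.csv"
    try:
        if not manifest.done(stage, [kin_csv]):
            K = kin.kinship_from_genotypes(G)
            kin.write_kinship_csv(K, kin_csv)
            manifest.record(stage, {}, [kin_csv])
        K = kin.read_kinship_csv(kin_csv)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: phenotype prep ------------------------------------------
    stage = "prep"
    adj_csv = out / "adjusted.csv"
    try:
        if not manifest.done(stage, [adj_csv]):
            adjusted = prepare_table(pheno, covars, diet_numeric=config.diet_numeric,
                                     outlier_sd=config.outlier_sd)
            adjusted.to_csv(adj_csv)
            manifest.record(stage, {"outlier_sd": config.outlier_sd}, [adj_csv])
        adjusted = pd.read_csv(adj_csv, index_col=0)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: heritability + filtering --------------------------------
    stage = "h2"
    h2_csv = out / "h2.csv"
    try:
        ests = {t: he_core.he_h2(adjusted[t].to_numpy(dtype=float), K, trait=t)
                for t in adjusted.columns}
        kept, excluded = he_core.filter_traits(ests.values())
        pd.DataFrame([{"Trait": e.trait, "h2": e.h2, "SE": e.se_corrected,
                       "p": e.p, "n": e.n_animals} for e in ests.values()]).to_csv(h2_csv, index=False)
        manifest.record(stage, {"h2_min": config.h2_min}, [h2_csv])
        logger.info("h2 stage: %d kept, %d excluded", len(kept), len(excluded))
        for est, reason in excluded:
            logger.info("excluded %s: %s", est.trait, reason)
        kept_names = [e.trait for e in kept]
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: r_g atlas ------------------------------------------------
    stage = "rg"
    rg_csv = out / "rg.csv"
    try:
        sub = adjusted[kept_names]
        R = rg_atlas.rg_matrix(sub, K, ests, alpha=config.alpha)
        rows = []
        for a in range(len(R.traits)):
            for b in range(a + 1, len(R.traits)):
                rows.append({"Trait1": R.traits[a], "Trait2": R.traits[b],
                             "rg": R.rg[a, b], "SE": R.se[a, b], "rg_p": R.p[a, b],
                             "h2_1": ests[R.traits[a]].h2, "h2_2": ests[R.traits[b]].h2,
                             "n_1": ests[R.traits[a]].n_animals, "n_2": ests[R.traits[b]].n_animals})
        pd.DataFrame(rows).to_csv(rg_csv, index=False)
        manifest.record(stage, {"bonferroni": R.bonferroni}, [rg_csv])
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: clustering + meta-traits ---------------------------------
    stage = "cluster"
    clusters_csv, meta_csv = out / "clusters.csv", out / "meta_traits.csv"
    try:
        rpg = rg_atlas.rpg_matrix(R)
        D = rg_atlas.rpg_to_distance(rpg.values, np.maximum(rpg.n_obs, 1))
        np.fill_diagonal(D, 0.0)
        D[~np.isfinite(D)] = np.nanmax(D[np.isfinite(D)]) if np.isfinite(D).any() else 1.0
        link = rg_atlas.ward_cluster(D)
        k_max = config.k_max or max(config.k_min, len(R.traits) - 1)
        sol = rg_atlas.sweep_k(link, sub, K, rpg, ests,
                               k_range=range(config.k_min, k_max + 1))
        pd.DataFrame({"Trait": list(sol.assignments), "Cluster": list(sol.assignments.values())}
                     ).to_csv(clusters_csv, index=False)
        metas = {}
        for c in sorted(set(sol.assignments.values())):
            members = [t for t, lab in sol.assignments.items() if lab == c]
            mt = rg_atlas.build_meta_trait(members, rpg, ests, sub)
            metas[f"C_{c}"] = mt.values
        meta_df = pd.DataFrame(metas, index=sub.index)
        meta_df.to_csv(meta_csv, na_rep="NA")
        manifest.record(stage, {"k": sol.k}, [clusters_csv, meta_csv])
        logger.info("cluster stage: k=%d mean h2 ratio %.3f", sol.k, sol.mean_h2_ratio)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: genome scans ---------------------------------------------
    stage = "scan"
    scans_dir = out / "scans"
    peaks_csv = out / "peaks.csv"
    try:
        scans_dir.mkdir(exist_ok=True)
        P = simdata.simulate_founder_probs(
            G.n_individuals, n_markers=min(200, config.n_markers),
            seed=config.stage_seed(stage),
        )
        peak_rows = []
        for name, vals in meta_df.items():
            res = scan_mod.genome_scan(vals.to_numpy(dtype=float), P, trait_name=name)
            res.to_frame().to_csv(scans_dir / f"{name}.csv", index=False)
            perm = scan_mod.permutation_threshold(
                vals.to_numpy(dtype=float), P, n_perm=max(20, config.n_perm // 10),
                alpha=config.alpha, seed=config.stage_seed(stage) + 1,
            )
            for pk in scan_mod.find_peaks(res, threshold=perm.alpha_threshold,
                                          drop=config.drop, peakdrop=config.peakdrop):
                peak_rows.append({"Trait": name, "Chr": pk.chromosome, "Pos": pk.position,
                                  "LOD": pk.lod, "CI_start": pk.ci_lo, "CI_end": pk.ci_hi,
                                  "VarExp": pk.variance_explained,
                                  "Threshold": perm.alpha_threshold})
        pd.DataFrame(peak_rows, columns=["Trait", "Chr", "Pos", "LOD", "CI_start",
                                         "CI_end", "VarExp", "Threshold"]).to_csv(peaks_csv, index=False)
        manifest.record(stage, {"alpha": config.alpha}, [peaks_csv])
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    logger.info("pipeline complete: %s", out)
    return out
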