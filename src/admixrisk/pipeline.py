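"""End-to-end orchestration.

Runs the full comparative-risk analysis in dependency order — simulate (or
load) genotypes → catalog filter → ancestry (LD prune, allele-sharing
distances, MDS, supervised fractions) → per-SNP ORs → meta-analysis →
resampling controls → PRS → group comparisons and the ancestry–risk
regression — writing every intermediate artifact plus a manifest JSON with
parameters, seed, and file checksums.

Configuration comes from a declarative YAML file (or an in-memory
:class:`PipelineConfig`); exactly one of a ``simulation`` block or explicit
``input`` paths must be present.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import compare as cmp
from . import genio, popgen, resampling, riskstats, simulate

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    output_dir: str
    seed: int
    # exactly one of these two:
    simulation: dict[str, Any] | None = None
    input: dict[str, str] | None = None  # vcf, catalog, reference_freqs, sample_populations
    contrast: tuple[str, str] = ("choco_like", "antioquia_like")
    trait: str = "trait_of_interest"
    p_threshold: float = cat.DEFAULT_P_THRESHOLD
    min_study_snps: int = cat.DEFAULT_MIN_STUDY_SNPS
    clump_window_bp: int = cat.DEFAULT_CLUMP_WINDOW_BP
    n_bootstrap: int = 10_000
    n_random_sets: int = 500_000
    ld_r2_threshold: float = 0.1
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    mds_dims: int = 2
    disease_traits: int = 40
    disease_snps_per_trait: int = 30

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input is None):
            raise ValueError(
                "exactly one of 'simulation' and 'input' must be configured"
            )
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "contrast" in raw:
        raw["contrast"] = tuple(raw["contrast"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _build_sim_config(block: dict[str, Any], seed: int) -> simulate.SimulationConfig:
    block = dict(block)
    profiles = block.pop("pop_profiles", None)
    kwargs: dict[str, Any] = {"seed": seed}
    if profiles is not None:
        kwargs["pop_profiles"] = tuple(
            simulate.PopulationProfile(
                p["label"], int(p["n_individuals"]), tuple(p["dirichlet_alpha"])
            )
            for p in profiles
        )
    for key in (
        "n_ancestral_pops", "n_snps", "n_risk_snps", "risk_shift_delta",
        "shift_target_ancestry", "missing_rate", "n_duplicate_snps",
    ):
        if key in block:
            kwargs[key] = block[key]
    for key in ("fst_per_pop", "ancestry_labels"):
        if key in block:
            kwargs[key] = tuple(block[key])
    return simulate.SimulationConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk).

    Any stage failure raises with the stage name in the message.  Outputs
    are pure functions of (inputs, parameters, seed): re-running an
    identical configuration reproduces every numeric artifact byte for
    byte.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "parameters": {
            "contrast": list(config.contrast),
            "trait": config.trait,
            "p_threshold": config.p_threshold,
            "min_study_snps": config.min_study_snps,
            "clump_window_bp": config.clump_window_bp,
            "n_bootstrap": config.n_bootstrap,
            "n_random_sets": config.n_random_sets,
            "ld_r2_threshold": config.ld_r2_threshold,
        },
        "stages": [],
    }

    def stage(name):
        t0 = time.time()
        log.info("stage %s: start", name)

        def done(outputs: list[Path]) -> None:
            manifest["stages"].append(
                {
                    "stage": name,
                    "outputs": {
                        str(p.relative_to(outdir)): _sha256(p) for p in outputs
                    },
                    "seconds": round(time.time() - t0, 3),
                }
            )
            log.info("stage %s: done (%.2fs)", name, time.time() - t0)

        return done

    try:
        # ------------------------------------------------------------------ inputs
        done = stage("inputs")
        if config.simulation is not None:
            sim_cfg = _build_sim_config(config.simulation, config.seed)
            study = simulate.simulate_study(sim_cfg)
            gm = study.genotypes
            disease_rows = simulate.generate_disease_catalog(
                sim_cfg,
                exclude_rsids=study.risk_set.rsids,
                n_traits=config.disease_traits,
                snps_per_trait=config.disease_snps_per_trait,
            )
            catalog_entries = study.catalog + disease_rows
            reference = popgen.ReferenceFrequencies(
                labels=sim_cfg.ancestry_labels,
                rsids=[v.id for v in gm.variants[: sim_cfg.n_snps]],
                freqs=study.truth.ancestral_freqs,
            )
            vcf_path = outdir / "genotypes.vcf"
            genio.write_vcf(gm, vcf_path)
            cat_path = outdir / "catalog.tsv"
            genio.write_catalog(catalog_entries, cat_path)
            ref_path = outdir / "reference_freqs.tsv"
            reference.to_frame().to_csv(ref_path, sep="\t", index=False)
            pop_path = outdir / "sample_populations.tsv"
            pd.DataFrame(
                {"sample": gm.samples, "population": gm.populations}
            ).to_csv(pop_path, sep="\t", index=False)
            simulate.write_truth_files(study.truth, gm, outdir)
            done([
                vcf_path, cat_path, ref_path, pop_path,
                outdir / "truth_ancestry_fractions.tsv",
                outdir / "truth_ancestral_freqs.tsv",
                outdir / "truth_risk_snps.tsv",
            ])
        else:
            paths = config.input
            pops_df = pd.read_csv(paths["sample_populations"], sep="\t")
            pop_map = dict(zip(pops_df["sample"], pops_df["population"]))
            gm = genio.read_vcf(paths["vcf"], populations=pop_map)
            catalog_entries = genio.read_catalog(paths["catalog"])
            reference = popgen.ReferenceFrequencies.from_tsv(
                paths["reference_freqs"]
            )
            done([])

        for pop in config.contrast:
            if gm.populations is None or pop not in gm.populations:
                raise ValueError(f"unknown population {pop!r} in contrast")

        # ----------------------------------------------------------- catalog filter
        done = stage("filter_catalog")
        audit = cat.FilterAudit()
        risk_set = cat.filter_catalog(
            catalog_entries,
            config.trait,
            p_threshold=config.p_threshold,
            min_study_snps=config.min_study_snps,
            clump_window_bp=config.clump_window_bp,
            audit=audit,
        )
        if risk_set.is_empty:
            raise ValueError(
                f"no catalog entries for trait {config.trait!r} survived filtering"
            )
        rs_path = outdir / "risk_snps.tsv"
        cat.write_risk_set(risk_set, rs_path)
        audit_path = outdir / "filter_audit.tsv"
        audit.to_frame().to_csv(audit_path, sep="\t", index=False)
        done([rs_path, audit_path])

        # ---------------------------------------------------------------- ancestry
        done = stage("ancestry")
        kept = popgen.ld_prune(
            gm,
            r2_threshold=config.ld_r2_threshold,
            window_snps=config.ld_window_snps,
            step_snps=config.ld_step_snps,
        )
        kept_set = set(kept)
        kept_idx = [i for i, v in enumerate(gm.variants) if v.id in kept_set]
        gm_pruned = gm.subset_variants(kept_idx)
        dm = popgen.allele_sharing_distance(gm_pruned)
        coords = popgen.project_mds(dm, n_dims=config.mds_dims)
        fractions = popgen.estimate_ancestry_supervised(gm_pruned, reference)
        dm_path = outdir / "distance_matrix.tsv"
        dm.to_frame().to_csv(dm_path, sep="\t")
        mds_path = outdir / "mds_coords.tsv"
        mds_df = pd.DataFrame(
            coords, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]
        )
        mds_df.insert(0, "sample", gm.samples)
        if gm.populations is not None:
            mds_df.insert(1, "population", gm.populations)
        mds_df.to_csv(mds_path, sep="\t", index=False)
        frac_path = outdir / "ancestry_fractions.tsv"
        fractions.to_frame().to_csv(frac_path, sep="\t", index=False)
        done([dm_path, mds_path, frac_path])

        # ---------------------------------------------------- alignment + frequencies
        done = stage("allele_frequencies")
        aligned = genio.align_risk_alleles(gm, risk_set)
        freq_df = popgen.allele_frequencies(aligned)
        freq_path = outdir / "frequency_table.tsv"
        freq_df.to_csv(freq_path, sep="\t", index=False)
        done([freq_path])

        # ----------------------------------------------------------------- or-meta
        done = stage("or_meta")
        pop_a, pop_b = config.contrast
        ors = riskstats.or_table(aligned, pop_a, pop_b)
        or_path = outdir / "or_table.tsv"
        riskstats.or_results_to_frame(ors).to_csv(or_path, sep="\t", index=False)
        meta_fixed = riskstats.meta_analyze(ors, model="fixed")
        meta_random = riskstats.meta_analyze(ors, model="random")
        meta_path = outdir / "meta_results.json"
        _write_json(
            {"fixed": vars(meta_fixed), "random": vars(meta_random)}, meta_path
        )
        done([or_path, meta_path])

        # ---------------------------------------------------------------- controls
        done = stage("controls")
        boot_null, boot_z = resampling.bootstrap_meta(
            ors, n_reps=config.n_bootstrap, seed=config.seed + 11
        )
        boot_path = outdir / "bootstrap_null.tsv"
        boot_null.to_frame().to_csv(boot_path, sep="\t", index=False)
        boot_json = outdir / "bootstrap_null.json"
        _write_json(boot_null.sidecar(boot_z), boot_json)

        trait_sets = cat.multi_trait_split(
            [e for e in catalog_entries if e.trait != config.trait],
            p_threshold=config.p_threshold,
            min_study_snps=config.min_study_snps,
            clump_window_bp=config.clump_window_bp,
        )
        pool_rsids: dict[str, cat.RiskEntry] = {}
        for rs in trait_sets.values():
            for e in rs.entries:
                pool_rsids.setdefault(e.rsid, e)
        pool_set = cat.RiskSNPSet("pool", list(pool_rsids.values()))
        pool_aligned = genio.align_risk_alleles(gm, pool_set)
        pool_ors = riskstats.or_table(pool_aligned, pop_a, pop_b)
        rand_null, rand_z = resampling.random_snpset_null(
            pool_ors,
            set_size=min(len(ors), len(pool_ors)),
            n_reps=config.n_random_sets,
            seed=config.seed + 13,
            observed=meta_fixed,
        )
        rand_path = outdir / "random_set_null.tsv"
        rand_null.to_frame().to_csv(rand_path, sep="\t", index=False)
        rand_json = outdir / "random_set_null.json"
        _write_json(rand_null.sidecar(rand_z), rand_json)

        pops = gm.by_population()
        scan_table, scan_z = resampling.disease_scan(
            pops[pop_a], pops[pop_b], trait_sets
        )
        scan_path = outdir / "disease_scan.tsv"
        scan_table.to_csv(scan_path, sep="\t", index=False)
        scan_json = outdir / "disease_scan.json"
        _write_json(
            {
                "kind": "disease_scan",
                "n_traits": int(scan_z.n),
                "z": scan_z.z,
                "p": scan_z.p,
                "mean_difference": scan_z.mean,
                "sd_difference": scan_z.sd,
            },
            scan_json,
        )
        done([boot_path, boot_json, rand_path, rand_json, scan_path, scan_json])

        # --------------------------------------------------------------------- prs
        done = stage("prs")
        prs = riskstats.polygenic_risk_score(aligned)
        prs_path = outdir / "prs.tsv"
        prs.to_frame().to_csv(prs_path, sep="\t", index=False)
        done([prs_path])

        # ----------------------------------------------------------------- compare
        done = stage("compare")
        group = cmp.group_prs_test(prs, groups=list(config.contrast))
        group_path = outdir / "group_test.json"
        _write_json(
            {
                "test": group.test,
                "statistic": group.statistic,
                "p_value": group.p_value,
                "groups": list(group.groups),
                "sizes": list(group.sizes),
                "means": list(group.means),
                "n_excluded": group.n_excluded,
            },
            group_path,
        )
        # regress PRS on the shift-target (first) ancestry fraction
        reg = cmp.ancestry_prs_regression(fractions, 0, prs)
        reg_path = outdir / "ancestry_regression.json"
        _write_json(reg.to_dict(), reg_path)
        dec_path = outdir / "ancestry_deciles.tsv"
        reg.decile_summary.to_csv(dec_path, sep="\t", index=False)
        done([group_path, reg_path, dec_path])
    except Exception as exc:
        stage_name = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise RuntimeError(
            f"pipeline failed after stage {stage_name!r}: {exc}"
        ) from exc

    manifest_path = outdir / "manifest.json"
    _write_json(manifest, manifest_path)
    return manifest
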