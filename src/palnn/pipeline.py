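"""Stage orchestration shared by the CLI and end-to-end tests.

Every stage reads upstream artifacts from the run directory, writes its own
artifacts plus a manifest entry (inputs, seeds, output hashes), and derives
its randomness from the master seed via a stable per-stage hash, so reruns
with identical inputs are idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution, evalbench, genotypes, nnmodel, nullsig, palcall, phenosim

logger = logging.getLogger(__name__)

STAGES = (
    "simulate-genotypes",
    "simulate-phenotype",
    "train",
    "attribute",
    "aggregate",
    "null-fit",
    "pvalues",
    "gwas-lr",
    "evaluate",
)


@dataclass
class RunConfig:
    out_dir: str = "palnn_run"
    genotypes_path: str | None = None  # read instead of simulating when set
    phenotypes_path: str | None = None
    # synthetic genotypes
    n_individuals: int = 2000
    n_positions: int = 5000
    block_size: int = 20
    haplotype_pool: int = 8
    bp_spacing: int = 5000
    # phenotype scenario
    k: float = 1.0
    n_causal: int = 20
    case_fraction: float = 0.1985
    # model / training
    model_preset: str | None = None  # "genome-wide" | "small" | None (size rule)
    m: int = 5
    m_null: int = 5
    epochs: int = 200
    null_epochs: int | None = None  # default: same as epochs
    batch_size: int = 256
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    input_mask_p: float = 0.5
    hidden_dropout_p: float = 0.1
    input_noise_sd: float = 0.1
    label_noise_sd: float = 0.1
    n_val_cases: int = 50
    n_val_controls: int = 50
    # PAL calling
    attribution_method: str = "IG"
    ig_steps: int = 50
    theta: str | float = "strict"  # "strict" | "relaxed" | percentile float
    r_threshold: float = 0.5
    block_gap: int = 100_000
    # significance
    n_reps: int = 100
    # misc
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def theta_percentile(self) -> float:
        if self.theta == "strict":
            return palcall.STRICT_PERCENTILE
        if self.theta == "relaxed":
            return palcall.RELAXED_PERCENTILE
        return float(self.theta)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    """Filesystem-backed run of the PAL detection pipeline."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"

    # ------------------------------------------------------------- plumbing

    def _record(self, stage: str, outputs: list[Path], **extra) -> None:
        manifest = {}
        if self.manifest_path.exists():
            manifest = json.loads(self.manifest_path.read_text())
        manifest[stage] = {
            "seed": stage_seed(self.config.master_seed, stage),
            "outputs": {p.name: _hash_file(p) for p in outputs if p.exists()},
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
            **extra,
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=2))

    def _require(self, stage: str, *paths: Path) -> None:
        missing = [str(p) for p in paths if not p.exists()]
        if missing:
            raise FileNotFoundError(
                f"stage {stage!r} requires missing upstream artifact(s): {missing}"
            )

    # --------------------------------------------------------------- stages

    def simulate_genotypes(self) -> genotypes.GenotypeMatrix:
        cfg = self.config
        seed = stage_seed(cfg.master_seed, "simulate-genotypes")
        if cfg.genotypes_path:
            g = genotypes.read_genotypes(cfg.genotypes_path)
        else:
            g = genotypes.generate_genotypes(
                cfg.n_individuals,
                cfg.n_positions,
                block_size=cfg.block_size,
                haplotype_pool=cfg.haplotype_pool,
                bp_spacing=cfg.bp_spacing,
                seed=seed,
            )
        path = self.out / "genotypes.traw"
        genotypes.write_traw(g, path)
        genotypes.write_variant_metadata(g, self.out / "variants.tsv")
        genotypes.write_generator_sidecar(
            self.out / "genotypes.json",
            seed=seed,
            n_individuals=g.n_individuals,
            n_positions=g.n_positions,
            block_size=cfg.block_size,
            haplotype_pool=cfg.haplotype_pool,
            bp_spacing=cfg.bp_spacing,
            source=cfg.genotypes_path or "synthetic",
        )
        self._record("simulate-genotypes", [path, self.out / "variants.tsv"])
        return g

    def load_genotypes(self) -> genotypes.GenotypeMatrix:
        path = self.out / "genotypes.traw"
        self._require("load-genotypes", path)
        return genotypes.read_genotypes(path)

    def simulate_phenotype(self) -> tuple[phenosim.PhenotypeSet, phenosim.EffectSpec]:
        cfg = self.config
        g = self.load_genotypes()
        seed = stage_seed(cfg.master_seed, "simulate-phenotype")
        ph, eff = phenosim.simulate_phenotypes(
            g, cfg.n_causal, cfg.k, case_fraction=cfg.case_fraction, seed=seed
        )
        ph.to_tsv(self.out / "phenotypes.tsv")
        eff.to_json(self.out / "effects.json")
        self._record(
            "simulate-phenotype",
            [self.out / "phenotypes.tsv", self.out / "effects.json"],
            k=cfg.k,
            n_causal=cfg.n_causal,
            tau=ph.tau,
            sigma2_genetic=ph.sigma2_genetic,
        )
        return ph, eff

    def load_labels(self) -> np.ndarray:
        path = self.out / "phenotypes.tsv"
        self._require("load-labels", path)
        return pd.read_csv(path, sep="\t")["y_binary"].to_numpy()

    def model_config(self, g: genotypes.GenotypeMatrix, seed: int) -> nnmodel.ModelConfig:
        cfg = self.config
        preset = {}
        if cfg.model_preset == "genome-wide":
            preset = dict(nnmodel.GENOME_WIDE_PRESET)
        elif cfg.model_preset == "small":
            preset = dict(nnmodel.SMALL_PRESET)
        elif cfg.model_preset is not None:
            raise ValueError(f"unknown model preset {cfg.model_preset!r}")
        preset.pop("input_size", None)
        return nnmodel.ModelConfig(
            input_size=g.n_positions,
            hidden1=preset.get("hidden1"),
            hidden2=preset.get("hidden2"),
            input_mask_p=preset.get("input_mask_p", cfg.input_mask_p),
            hidden_dropout_p=cfg.hidden_dropout_p,
            learning_rate=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            label_noise_sd=cfg.label_noise_sd,
            input_noise_sd=cfg.input_noise_sd,
            n_val_cases=cfg.n_val_cases,
            n_val_controls=cfg.n_val_controls,
            seed=seed,
        )

    def _train_group(self, null: bool) -> list[nnmodel.TrainedModel]:
        cfg = self.config
        g = self.load_genotypes()
        labels = self.load_labels()
        stage = "train-null" if null else "train"
        base_seed = stage_seed(cfg.master_seed, stage)
        count = cfg.m_null if null else cfg.m
        seeds = [base_seed + i for i in range(count)]
        config = self.model_config(g, seeds[0])
        if null and cfg.null_epochs is not None:
            config = dataclasses.replace(config, epochs=cfg.null_epochs)
        models = nnmodel.train_ensemble(
            g.values.astype(np.float32),
            labels,
            config,
            seeds,
            permute_labels=null,
            permutation_seed=stage_seed(cfg.master_seed, stage + "-perm"),
        )
        sub = self.out / ("null_models" if null else "models")
        sub.mkdir(exist_ok=True)
        outputs = []
        for model in models:
            stem = sub / f"model_{model.config.seed}"
            model.save(stem)
            outputs.append(stem.with_suffix(".json"))
            pd.DataFrame(model.history).to_csv(
                stem.with_suffix(".losses.tsv"), sep="\t", index=False
            )
        self._record(stage, outputs, seeds=seeds)
        return models

    def train(self) -> list[nnmodel.TrainedModel]:
        return self._train_group(null=False)

    def train_null(self) -> list[nnmodel.TrainedModel]:
        return self._train_group(null=True)

    def _load_models(self, null: bool) -> list[nnmodel.TrainedModel]:
        sub = self.out / ("null_models" if null else "models")
        stems = sorted(sub.glob("model_*.json"))
        self._require("load-models", sub, *stems[:1] if stems else [sub / "model"])
        return [nnmodel.TrainedModel.load(p.with_suffix("")) for p in stems]

    def _attribute_group(self, null: bool) -> palcall.MASMatrix:
        cfg = self.config
        g = self.load_genotypes()
        labels = self.load_labels()
        models = self._load_models(null)
        seed = stage_seed(cfg.master_seed, "attribute-null" if null else "attribute")
        x = g.values.astype(np.float32)
        vectors = []
        for model in models:
            vec = attribution.mas_for_model(
                model,
                x,
                labels,
                method=cfg.attribution_method,
                n_steps=cfg.ig_steps,
                seed=seed + model.config.seed,
            )
            vectors.append(vec)
        A = palcall.MASMatrix(
            A=np.stack([v.values for v in vectors]),
            model_seeds=[m.config.seed for m in models],
            method=cfg.attribution_method.upper(),
        )
        name = "null_mas.tsv" if null else "mas.tsv"
        df = pd.DataFrame(
            A.A.T, columns=[f"model_{s}" for s in A.model_seeds]
        )
        df.insert(0, "id", g.variants["id"])
        df.to_csv(self.out / name, sep="\t", index=False)
        self._record(
            "attribute-null" if null else "attribute",
            [self.out / name],
            method=cfg.attribution_method,
        )
        return A

    def attribute(self) -> palcall.MASMatrix:
        return self._attribute_group(null=False)

    def attribute_null(self) -> palcall.MASMatrix:
        return self._attribute_group(null=True)

    def load_mas(self, null: bool = False) -> palcall.MASMatrix:
        path = self.out / ("null_mas.tsv" if null else "mas.tsv")
        self._require("load-mas", path)
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c.startswith("model_")]
        return palcall.MASMatrix(
            A=df[cols].to_numpy().T,
            model_seeds=[int(c.split("_", 1)[1]) for c in cols],
            method=self.config.attribution_method.upper(),
        )

    def aggregate(self) -> palcall.PALReport:
        cfg = self.config
        g = self.load_genotypes()
        A = self.load_mas()
        report = palcall.aggregate(A, q=cfg.theta_percentile())
        report.signals = palcall.clump_cross_model(
            report.per_model_detected,
            g,
            r_threshold=cfg.r_threshold,
            amas={j: report.amas_value(j) for j in report.detected_union},
        )
        report.to_tsv(self.out / "palreport.tsv", variants=g.variants)
        (self.out / "palreport.json").write_text(json.dumps(report.summary(), indent=2))
        self._record(
            "aggregate", [self.out / "palreport.tsv", self.out / "palreport.json"]
        )
        return report

    def null_fit(self) -> nullsig.NullModel:
        A_null = self.load_mas(null=True)
        pooled = A_null.A.ravel()
        null = nullsig.fit_halfnormal(pooled)
        try:
            null.fit_table = nullsig.compare_tail_distributions(pooled)
            null.tail_quantile = 0.999
        except ValueError as exc:
            logger.warning("tail comparison skipped: %s", exc)
        payload = {
            "sigma": null.sigma,
            "n_pooled": null.n_pooled,
            "tail_quantile": null.tail_quantile,
        }
        (self.out / "null_fit.json").write_text(json.dumps(payload, indent=2))
        if null.fit_table:
            pd.DataFrame(
                [
                    {k: row[k] for k in ("name", "k", "loglik", "aic", "bic")}
                    for row in null.fit_table
                ]
            ).to_csv(self.out / "null_fit_table.tsv", sep="\t", index=False)
        self._record("null-fit", [self.out / "null_fit.json"], sigma=null.sigma)
        return null

    def pvalues(self) -> nullsig.PValueSet:
        cfg = self.config
        fit_path = self.out / "null_fit.json"
        self._require("pvalues", fit_path)
        null = nullsig.NullModel(
            **{
                k: v
                for k, v in json.loads(fit_path.read_text()).items()
                if k in ("sigma", "n_pooled", "tail_quantile")
            }
        )
        A = self.load_mas()
        report = self.aggregate_in_memory(A)
        pv = nullsig.estimate_pvalues(
            A,
            report,
            null,
            n_reps=cfg.n_reps,
            seed=stage_seed(cfg.master_seed, "pvalues"),
        )
        df = pd.DataFrame(
            {
                "position": sorted(pv.pvalues),
                "p": [pv.pvalues[j] for j in sorted(pv.pvalues)],
                "at_floor": [j in pv.at_floor for j in sorted(pv.pvalues)],
            }
        )
        df.to_csv(self.out / "pvalues.tsv", sep="\t", index=False)
        (self.out / "pvalues.json").write_text(
            json.dumps(
                {
                    "n_reps": pv.n_reps,
                    "pool_size": pv.pool_size,
                    "floor": pv.floor,
                    "sigma": null.sigma,
                },
                indent=2,
            )
        )
        self._record("pvalues", [self.out / "pvalues.tsv", self.out / "pvalues.json"])
        return pv

    def aggregate_in_memory(self, A: palcall.MASMatrix) -> palcall.PALReport:
        return palcall.aggregate(A, q=self.config.theta_percentile())

    def gwas_lr(self) -> evalbench.AssociationResult:
        g = self.load_genotypes()
        labels = self.load_labels()
        covs = genotypes.pca_covariates(g, 3)
        result = evalbench.logistic_gwas(g, labels, covariates=covs)
        result.to_tsv(self.out / "gwas_lr.tsv")
        self._record(
            "gwas-lr",
            [self.out / "gwas_lr.tsv"],
            bonferroni_threshold=result.bonferroni_threshold,
        )
        return result

    def evaluate(self) -> dict:
        cfg = self.config
        g = self.load_genotypes()
        eff = phenosim.EffectSpec.from_json(self.out / "effects.json")
        A = self.load_mas()
        report = self.aggregate_in_memory(A)
        detected = sorted(report.detected_union | report.pal_amas)
        blocks = palcall.block_clump_distance(detected, g.variants, gap=cfg.block_gap)
        evaluation = evalbench.label_detections(
            blocks, eff.all_positions, g.variants, window=cfg.block_gap
        )
        metrics = evalbench.precision_recall(evaluation, n_causal=eff.n_causal)
        breakdown = evalbench.effect_type_breakdown(evaluation, eff)
        summary = {
            "tp": evaluation.tp,
            "fp": evaluation.fp,
            "fn": evaluation.fn,
            "recall_denominator": "causal positions",
            **metrics,
            "effect_breakdown": breakdown,
        }
        (self.out / "evaluation.json").write_text(json.dumps(summary, indent=2))
        self._record("evaluate", [self.out / "evaluation.json"])
        return summary

    # ----------------------------------------------------------------- runner

    def run_stage(self, stage: str) -> None:
        dispatch = {
            "simulate-genotypes": self.simulate_genotypes,
            "simulate-phenotype": self.simulate_phenotype,
            "train": lambda: (self.train(), self.train_null()),
            "attribute": lambda: (self.attribute(), self.attribute_null()),
            "aggregate": self.aggregate,
            "null-fit": self.null_fit,
            "pvalues": self.pvalues,
            "gwas-lr": self.gwas_lr,
            "evaluate": self.evaluate,
        }
        if stage == "all":
            for s in STAGES:
                logger.info("=== stage %s ===", s)
                dispatch[s]()
            return
        if stage not in dispatch:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
        dispatch[stage]()
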