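"""End-to-end orchestration: from inputs (real files or a synthetic
study) to the per-site diversity table, correlation screen, interaction
models, formatted report, median-split summaries, and a machine-readable
JSON dump of every fitted model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import diversity as dv
from . import fauna as fa
from . import inference as inf
from . import synthdata as sd
from . import vegetation as vg
from .errors import PipelineStageError
from .phylo import parse_newick, patristic_matrix

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "fit_all_models", "TRAITS", "RESPONSES"]

TRAITS = ("sla", "ldmc")

# response column -> human label; order mirrors the report layout
RESPONSES = {
    "abund_mite": "Mites",
    "abund_springtail": "Springtails",
    "abund_earthworm": "Earthworms",
    "abund_nematode": "Nematodes",
    "abund_earthworm_epigeic": "Epigeic earthworms",
    "abund_earthworm_endogeic": "Endogeic earthworms",
    "abund_springtail_hemiedaphic": "Hemiedaphic springtails",
    "abund_springtail_euedaphic": "Euedaphic springtails",
    "abund_mite_actinedid": "Actinedid mites",
    "abund_mite_gamasid": "Gamasid mites",
    "abund_nematode_phytophage": "Phytophagous nematodes",
    "abund_nematode_carnivore": "Carnivorous nematodes",
    "structure_index": "Nematode Structure Index",
    "simpson_earthworm": "Earthworm diversity",
    "simpson_springtail": "Springtail diversity",
    "simpson_nematode": "Nematode diversity",
}


@dataclass
class RunConfig:
    """Inputs for one run. Either ``synthetic`` (a SynthConfig) or the four
    file paths must be provided."""

    outdir: str | Path = "phylofauna_out"
    tree: str | None = None
    survey: str | None = None
    traits: str | None = None
    fauna: str | None = None
    synthetic: sd.SynthConfig | None = None
    null_replicates: int = 999
    seed: int = 0
    outlier_threshold: float = inf.OUTLIER_THRESHOLD
    max_outliers: int = inf.MAX_OUTLIERS

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            if "fauna_groups" in syn:
                syn["fauna_groups"] = tuple(
                    sd.FaunaGroupSpec(**g) for g in syn["fauna_groups"]
                )
            if "richness" in syn:
                syn["richness"] = tuple(syn["richness"])
            for key in ("tau_phylo", "tau_trait"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = sd.SynthConfig(**syn)
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


@_stage("vegetation")
def _load_vegetation(cfg: RunConfig):
    survey = vg.read_survey(cfg.survey)
    community = vg.community_matrix(survey)
    traits = vg.read_traits(cfg.traits).set_index("species")
    return community, traits


@_stage("phylogeny")
def _load_tree(cfg: RunConfig, species):
    with open(cfg.tree) as fh:
        tree = parse_newick(fh.read())
    return patristic_matrix(tree, list(species))


@_stage("diversity")
def _diversity(community, dmat, traits, cfg: RunConfig):
    null = dv.NullModelSpec(replicates=cfg.null_replicates, seed=cfg.seed)
    table = dv.community_diversity(community, dmat, traits, null=null)
    log.info("diversity computed for %d sites (%d null replicates)", len(table), null.replicates)
    return table


@_stage("fauna")
def _fauna(cfg: RunConfig, study):
    table = study.fauna if study is not None else pd.read_csv(cfg.fauna, sep="\t")
    return fa.summarize_fauna(table)


def fit_all_models(
    analysis: pd.DataFrame,
    responses=None,
    traits=TRAITS,
    max_outliers: int = inf.MAX_OUTLIERS,
    outlier_threshold: float = inf.OUTLIER_THRESHOLD,
) -> list[inf.ModelResult]:
    """One model per trait × response. Abundance responses are
    log10(x+1)-transformed; Simpson and Structure Index enter untransformed."""
    responses = responses or [r for r in RESPONSES if r in analysis.columns]
    # drop the source factor when absent or constant (single-source data)
    veg = "veg_source" if "veg_source" in analysis and analysis["veg_source"].nunique() > 1 else None
    results = []
    for trait in traits:
        for resp in responses:
            data = analysis.copy()
            col = resp
            if resp.startswith("abund_"):
                col = f"log_{resp}"
                data[col] = fa.log_abundance(data[resp].to_numpy())
            spec = inf.ModelSpec(
                response=col,
                trait=trait,
                veg_factor=veg,
                max_outliers=max_outliers,
                outlier_threshold=outlier_threshold,
            )
            res = inf.fit_interaction_model(data, spec)
            log.info(
                "fitted %s ~ %s: n=%d, excluded=%s", col, trait, res.n_used, res.excluded
            )
            results.append(res)
    return results


def run_study(cfg: RunConfig) -> dict:
    """Run the whole analysis and write the report bundle to ``cfg.outdir``.

    Outputs: diversity.tsv, fauna_summary.tsv, analysis_table.tsv,
    correlations_r.tsv / correlations_p.tsv, trait_vs_phylo.tsv,
    report.tsv, report.txt, median_split.tsv and models.json. The bundle
    is a pure function of inputs + seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    study = None
    if cfg.synthetic is not None:
        study = sd.generate_study(cfg.synthetic)
        community, traits = study.community, study.traits
        dmat = patristic_matrix(study.tree, list(community.columns))
        div = study.diversity
        site_table = study.site_table
    else:
        community, traits = _load_vegetation(cfg)
        dmat = _load_tree(cfg, community.columns)
        div = _diversity(community, dmat, traits, cfg)
        site_table = pd.DataFrame(
            {"veg_source": 0}, index=community.index
        )  # single-source default; real runs may join their own covariates

    fauna_summary = _fauna(cfg, study)
    veg_pcs = inf.vegetation_factors(community)

    analysis = div.join(fauna_summary, how="inner").join(site_table).join(veg_pcs)

    # Fig 3 analogue: trait diversity ~ phylogenetic diversity
    trait_vs_phylo = []
    for trait in TRAITS:
        sub = analysis[["ses_mpd", f"rao_{trait}"]].dropna()
        import scipy.stats as st

        fitres = st.linregress(sub["ses_mpd"], sub[f"rao_{trait}"])
        trait_vs_phylo.append(
            {
                "trait": trait,
                "slope": fitres.slope,
                "r2": fitres.rvalue**2,
                "p": fitres.pvalue,
                "n": len(sub),
            }
        )
    trait_vs_phylo = pd.DataFrame(trait_vs_phylo)

    screen_cols = [c for c in analysis.columns if analysis[c].dtype.kind in "if"]
    r, p = inf.pearson_screen(analysis[screen_cols])

    results = fit_all_models(
        analysis,
        max_outliers=cfg.max_outliers,
        outlier_threshold=cfg.outlier_threshold,
    )
    report = inf.build_report(results)

    labels, threshold = inf.median_split(analysis["ses_mpd"])
    split = analysis.join(labels)
    split_summary = (
        split.groupby("phylodiv_group")[
            [c for c in RESPONSES if c in split.columns] + ["ses_mpd"]
        ]
        .mean()
        .reset_index()
    )

    div.to_csv(outdir / "diversity.tsv", sep="\t")
    fauna_summary.to_csv(outdir / "fauna_summary.tsv", sep="\t")
    analysis.to_csv(outdir / "analysis_table.tsv", sep="\t")
    r.to_csv(outdir / "correlations_r.tsv", sep="\t")
    p.to_csv(outdir / "correlations_p.tsv", sep="\t")
    trait_vs_phylo.to_csv(outdir / "trait_vs_phylo.tsv", sep="\t", index=False)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    (outdir / "report.txt").write_text(
        report.to_string(index=False)
        + "\n\nTwo-sided p-values; no multiple-testing correction.\n"
        + f"Median split threshold (ses_mpd): {threshold:.4f}\n"
    )
    split_summary.to_csv(outdir / "median_split.tsv", sep="\t", index=False)

    models = {
        "median_split_threshold": threshold,
        "models": [res.to_dict() for res in results],
        "null_replicates": cfg.null_replicates,
        "null_scheme": "taxa-shuffle",
        "seed": cfg.seed,
    }
    with open(outdir / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, sort_keys=True, allow_nan=True)

    if cfg.synthetic is not None:
        study.community.to_csv(outdir / "community.tsv", sep="\t")
        study.traits.to_csv(outdir / "traits.tsv", sep="\t")
        study.fauna.to_csv(outdir / "fauna.tsv", sep="\t", index=False)
        (outdir / "tree.nwk").write_text(study.tree.to_newick() + "\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(study.truth, fh, indent=2, sort_keys=True)

    return models
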