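"""Per-gene genotype-phenotype association analysis and classification.

For each candidate gene this module runs the full chain of evidence:

1. fit the global and local MG94xREV codon models on the time tree pruned to
   the gene's species and test for branch-to-branch molecular rate variation
   (likelihood-ratio D; genes without significant variation are not analysed
   further);
2. root the fitted dN and dS branch trees on the outgroup, drop it, and sum
   branch values root-to-tip per species (R_dN, R_dS); sum the rate-scaled
   phenotypic tree the same way (R_phen);
3. run two Bayesian PGLS models on the time tree —
   model i:  testes mass ~ R_dN + R_dS + body mass,
   model ii: R_phen ~ R_dN + R_dS + testes mass + body mass —
   (all variables log10) and read off the R_dN coefficients;
4. classify the gene from the significance and sign of the R_dN effect on
   the phenotype (model i) and on the phenotypic rate (model ii):

   =============  ============  ==============================
   rate (ii)      phenotype (i) label
   =============  ============  ==============================
   sig, positive  ns            bidirectional_rapid_driver
   sig, positive  sig           directional_rapid_driver
   sig, negative  ns            moderator
   sig, negative  sig           directional_moderator
   ns             sig           directional_nonrapid_driver
   ns             ns            no_association
   =============  ============  ==============================

Leave-one-species-out robustness reruns both PGLS models once per species
with the molecular and phenotypic rate estimates held fixed.

No multiple-testing correction is applied across genes; the design's guard
against false positives is rerunning the same pipeline on control genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_mg94 as cm
from .pgls import PglsConfig, build_pgls_spec, pgls_mcmc
from .treedata import (
    BranchValueMap,
    Phylogeny,
    phylo_covariance,
    prune_to_tips,
    root_to_tip_sum,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenePhenConfig",
    "GeneAssociationResult",
    "run_gene_association",
    "classify_gene",
    "loo_robustness",
]

LABELS = (
    "bidirectional_rapid_driver",
    "directional_rapid_driver",
    "moderator",
    "directional_moderator",
    "directional_nonrapid_driver",
    "no_association",
)


@dataclass
class GenePhenConfig:
    min_overlap: int = 10          # species floor for the regressions
    lrt_alpha: float = 0.001       # gate: analyse only genes with rate variation
    px_alpha: float = 0.05         # significance threshold on p_x
    pgls: PglsConfig = field(default_factory=lambda: PglsConfig(iterations=15_000))
    codon_max_sweeps: int = 3


@dataclass
class GeneAssociationResult:
    """Everything the per-gene analysis produced, JSON-serialisable."""

    gene: str
    status: str                    # "ok" | "skipped_overlap" | "skipped_lrt"
    n_taxa: int
    lrt_D: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None
    model_i: dict | None = None
    model_ii: dict | None = None
    label: str | None = None
    r_dn: dict[str, float] = field(default_factory=dict)
    r_ds: dict[str, float] = field(default_factory=dict)
    r_phen: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "gene": self.gene, "status": self.status, "n_taxa": self.n_taxa,
            "lrt": {"D": self.lrt_D, "df": self.lrt_df, "p": self.lrt_p},
            "model_i": self.model_i, "model_ii": self.model_ii,
            "label": self.label,
            "R_dN": self.r_dn, "R_dS": self.r_ds, "R_phen": self.r_phen,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def _rtt_table(gene: str, overlap: list[str], traits: pd.DataFrame,
               r_dn, r_ds, r_phen) -> pd.DataFrame:
    tr = traits.set_index("species").loc[overlap]
    return pd.DataFrame({
        "species": overlap,
        "testes": tr["testes_mass_log10"].to_numpy(),
        "body": tr["body_mass_log10"].to_numpy(),
        "R_dN": np.log10([r_dn[s] for s in overlap]),
        "R_dS": np.log10([r_ds[s] for s in overlap]),
        "R_phen": np.log10([r_phen[s] for s in overlap]),
    })


def run_gene_association(
    gene: str,
    aln: cm.CodonAlignment,
    traits: pd.DataFrame,
    time_tree: Phylogeny,
    rt_tree: Phylogeny,
    outgroup: str,
    config: GenePhenConfig | None = None,
    seed: int = 0,
) -> GeneAssociationResult:
    """Run the full per-gene analysis (codon fits, LRT gate, path sums, both
    PGLS models, classification).  Deterministic given ``seed``.

    Insufficient species overlap or a non-significant molecular-rate LRT
    yields a structured skip record rather than an error.
    """
    config = config or GenePhenConfig()
    tree_tips = set(time_tree.tip_labels)
    trait_sp = set(traits["species"])
    aln_sp = set(aln.species)
    overlap = sorted((aln_sp - {outgroup}) & trait_sp & tree_tips)
    if len(overlap) < config.min_overlap:
        return GeneAssociationResult(gene=gene, status="skipped_overlap",
                                     n_taxa=len(overlap))

    # --- molecular rate variation -------------------------------------
    g = cm.fit_global(aln, time_tree, seed=seed)
    l = cm.fit_local(aln, time_tree, seed=seed, init=g,
                     max_sweeps=config.codon_max_sweeps)
    D, df, p = cm.lrt_global_vs_local(g, l)
    if p >= config.lrt_alpha:
        return GeneAssociationResult(gene=gene, status="skipped_lrt",
                                     n_taxa=len(overlap),
                                     lrt_D=D, lrt_df=df, lrt_p=p)

    dn_tree, ds_tree, dn_map, ds_map = cm.branch_value_trees(l, outgroup)
    r_dn = root_to_tip_sum(dn_tree, dn_map).totals
    r_ds = root_to_tip_sum(ds_tree, ds_map).totals
    r_phen = root_to_tip_sum(rt_tree, BranchValueMap.from_lengths(rt_tree)).totals

    overlap = sorted(set(overlap) & set(r_dn) & set(r_phen))
    data = _rtt_table(gene, overlap, traits, r_dn, r_ds, r_phen)

    sub_tree = prune_to_tips(time_tree, overlap)
    V, order = phylo_covariance(sub_tree, overlap)

    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(2 ** 31, size=2)
    spec_i = build_pgls_spec(data, "testes", ["R_dN", "R_dS", "body"], V, order)
    post_i = pgls_mcmc(spec_i, config.pgls, seed=int(s1))
    spec_ii = build_pgls_spec(data, "R_phen", ["R_dN", "R_dS", "testes", "body"],
                              V, order)
    post_ii = pgls_mcmc(spec_ii, config.pgls, seed=int(s2))

    result = GeneAssociationResult(
        gene=gene, status="ok", n_taxa=len(overlap),
        lrt_D=D, lrt_df=df, lrt_p=p,
        model_i=post_i.to_dict(), model_ii=post_ii.to_dict(),
        r_dn={s: float(r_dn[s]) for s in overlap},
        r_ds={s: float(r_ds[s]) for s in overlap},
        r_phen={s: float(r_phen[s]) for s in overlap},
    )
    result.label = classify_gene(result, alpha=config.px_alpha)
    return result


def classify_gene(result: GeneAssociationResult, alpha: float = 0.05) -> str:
    """Map the two R_dN effects to one of the six association categories.

    The *rate* axis is the R_dN coefficient in model ii (phenotypic rate as
    response); the *phenotype* axis is the R_dN coefficient in model i.  The
    map is total over the significance/sign grid.
    """
    if result.model_i is None or result.model_ii is None:
        raise ValueError("gene was not analysed (missing PGLS results)")
    rate = result.model_ii["coefficients"]["R_dN"]
    phen = result.model_i["coefficients"]["R_dN"]
    rate_sig = rate["p_x"] < alpha
    phen_sig = phen["p_x"] < alpha
    if rate_sig and rate["mean"] > 0:
        return "directional_rapid_driver" if phen_sig else "bidirectional_rapid_driver"
    if rate_sig:
        return "directional_moderator" if phen_sig else "moderator"
    return "directional_nonrapid_driver" if phen_sig else "no_association"


def loo_robustness(
    result: GeneAssociationResult,
    traits: pd.DataFrame,
    time_tree: Phylogeny,
    config: GenePhenConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-species-out reruns of both PGLS models.

    Molecular and phenotypic rate estimates are held fixed (paths re-pruned);
    each exclusion reruns only the regressions.  A failing rerun is recorded
    and the loop continues.  Returns one row per excluded species with the
    R_dN coefficient sign and p_x under both models.
    """
    config = config or GenePhenConfig()
    if result.status != "ok":
        raise ValueError("robustness requires a completed gene analysis")
    species = sorted(result.r_dn)
    rng = np.random.default_rng(seed)
    rows = []
    for excl in species:
        keep = [s for s in species if s != excl]
        try:
            data = _rtt_table(result.gene, keep, traits,
                              result.r_dn, result.r_ds, result.r_phen)
            sub = prune_to_tips(time_tree, keep)
            V, order = phylo_covariance(sub, keep)
            s1, s2 = rng.integers(2 ** 31, size=2)
            post_i = pgls_mcmc(
                build_pgls_spec(data, "testes", ["R_dN", "R_dS", "body"], V, order),
                config.pgls, seed=int(s1))
            post_ii = pgls_mcmc(
                build_pgls_spec(data, "R_phen", ["R_dN", "R_dS", "testes", "body"],
                                V, order),
                config.pgls, seed=int(s2))
            ci = post_i.to_dict()["coefficients"]["R_dN"]
            cii = post_ii.to_dict()["coefficients"]["R_dN"]
            rows.append((excl, "ok", ci["mean"], ci["p_x"], cii["mean"], cii["p_x"]))
        except Exception as exc:  # keep going; record the failure
            logger.warning("leave-one-out rerun failed for %s: %s", excl, exc)
            rows.append((excl, f"failed: {exc}", np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["excluded", "status", "model_i_mean", "model_i_px",
                       "model_ii_mean", "model_ii_px"])


# ---------------------------------------------------------------------------
# Whole-pipeline driver (used by the CLI and the benchmark tests)
# ---------------------------------------------------------------------------


def run_pipeline(
    tree: Phylogeny,
    traits: pd.DataFrame,
    alignments: dict[str, cm.CodonAlignment],
    outgroup: str,
    config: GenePhenConfig | None = None,
    varrates_config=None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> dict[str, GeneAssociationResult]:
    """Estimate the phenotypic rate tree once, then analyse every gene.

    The variable-rates model runs on the tree pruned to the trait species
    (outgroup excluded); its median-rate-scaled tree supplies R_phen to all
    genes.  Results are returned keyed by gene and, if ``outdir`` is given,
    written as JSON.
    """
    from .varrates import VarRatesConfig, design_from_traits, median_rate_tree, varrates_mcmc

    config = config or GenePhenConfig()
    varrates_config = varrates_config or VarRatesConfig(iterations=300_000)
    rng = np.random.default_rng(seed)
    vr_seed = int(rng.integers(2 ** 31))

    pheno_species = sorted(set(traits["species"]) & set(tree.tip_labels) - {outgroup})
    pheno_tree = prune_to_tips(tree, pheno_species)
    design = design_from_traits(
        traits[traits["species"].isin(pheno_species)], pheno_species)
    trace = varrates_mcmc(design, pheno_tree, varrates_config, seed=vr_seed)
    _, rt_tree = median_rate_tree(trace, pheno_tree)

    results: dict[str, GeneAssociationResult] = {}
    for gene in sorted(alignments):
        gseed = int(rng.integers(2 ** 31))
        results[gene] = run_gene_association(
            gene, alignments[gene], traits, tree, rt_tree, outgroup,
            config=config, seed=gseed)
        logger.info("gene %s: %s (label=%s)", gene, results[gene].status,
                    results[gene].label)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for gene, res in results.items():
            (outdir / f"{gene}.json").write_text(res.to_json() + "\n")
        summary = pd.DataFrame(
            [(g, r.status, r.n_taxa, r.lrt_D, r.lrt_p, r.label)
             for g, r in results.items()],
            columns=["gene", "status", "n_taxa", "D", "lrt_p", "label"])
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return results
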