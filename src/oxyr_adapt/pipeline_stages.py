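"""Stage implementations behind the `oxyr-adapt` pipeline.

Each stage reads its inputs from the shared output directory (produced by an
earlier stage) and writes TSV/JSON artifacts; `StageError` carries an
actionable message naming any missing artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import oxyr
from .allele_scan import (
    AlleleCollection,
    ConstitutiveReferenceSet,
    call_substitutions,
    screen_constitutive,
    translate_and_dedup,
)
from .expression import ExpressionMatrix, center_to_reference
from .growth_phenotype import dose_response_table
from .imodulon import activity_summary, define_membership, match_regulon, robust_ica
from .mutations import MutationRecord
from .proteome_cost import ProteomeCostModel, regulon_cost
from .structure_proximity import (
    classify_mutation,
    proximity_matrix,
    read_structure,
    write_pdb,
)
from .synthetic_data import (
    ModulonSpec,
    PlantedVariant,
    back_translate,
    simulate_alleles,
    simulate_expression,
    simulate_growth_curves,
    simulate_structure,
)


class StageError(RuntimeError):
    pass


@dataclass
class StageContext:
    out_dir: Path
    config: object  # PipelineConfig


def _require(ctx: StageContext, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = ctx.out_dir / name
        if not p.exists():
            raise StageError(
                f"missing artifact {name!r} in {ctx.out_dir} "
                "(run the `simulate` stage or supply the file)"
            )
        paths.append(p)
    return paths


# -- demo study conditions --------------------------------------------------

def demo_modulons() -> list[ModulonSpec]:
    """Two planted i-modulons mirroring the regulators the analysis tracks.

    The OxyR group carries the peroxide-defense genes with strong activation
    in the evolved conditions; the SoxS group (superoxide response) has no
    planted wt-vs-evolved difference and serves as the negative control.
    Member weights are signed and roughly zero-mean, the regime in which ICA
    weight vectors live (each component carries both up- and down-responding
    genes) and in which disjoint planted sources stay uncorrelated.
    """
    oxyr_genes = ["ahpC", "ahpF", "katG", "dps", "sufA", "sufB", "sufC", "grxA",
                  "trxC", "oxyS", "hemH", "mntH", "fur", "katE", "gorA",
                  "yaaA", "ybjM", "xthA", "uxuA", "fhuF"]
    soxs_genes = ["sodA", "fumC", "zwf", "fpr", "nfo", "acnA", "micF", "marA",
                  "inaA", "fldA", "fldB", "ribA", "nfsA", "ygfZ", "poxB",
                  "acrA", "acrB", "tolC", "mdtG", "rimK"]
    rng = np.random.default_rng(2019)

    def signed(genes):
        mags = rng.uniform(0.6, 1.4, len(genes))
        signs = np.where(np.arange(len(genes)) % 2 == 0, 1.0, -1.0)
        return {g: float(m * s) for g, m, s in zip(genes, mags, signs)}

    return [
        ModulonSpec(
            name="OxyR",
            weights=signed(oxyr_genes),
            activity_by_condition={"wt": 0.0, "gmos": 0.0,
                                   "evolved1": 8.0, "evolved2": 8.0},
        ),
        ModulonSpec(
            name="SoxS",
            weights=signed(soxs_genes),
            activity_by_condition={"wt": 0.0, "gmos": 3.0,
                                   "evolved1": 0.0, "evolved2": 0.0},
        ),
    ]


DEMO_CONDITIONS = [("wt", 3), ("gmos", 3), ("evolved1", 3), ("evolved2", 3)]


def demo_known_regulons() -> dict[str, set[str]]:
    return {m.name: m.member_genes for m in demo_modulons()}


# -- stages ------------------------------------------------------------------

def stage_simulate(ctx: StageContext) -> list[Path]:
    cfg = ctx.config
    out = ctx.out_dir
    params = cfg.simulate
    seed = cfg.seed
    produced = []

    # expression
    em, S_true, A_true = simulate_expression(
        demo_modulons(), DEMO_CONDITIONS, noise_sd=params["noise_sd"],
        seed=seed, n_genes=params["n_genes"], reference_condition="wt",
    )
    em.to_tsv(out / "expression.tsv", out / "expression_meta.tsv")
    S_true.to_csv(out / "S_true.tsv", sep="\t", index_label="gene_id")
    A_true.to_csv(out / "A_true.tsv", sep="\t", index_label="component")
    produced += [out / "expression.tsv", out / "expression_meta.tsv",
                 out / "S_true.tsv", out / "A_true.tsv"]

    # alleles: plant the natural-isolate substitution set
    protein = oxyr.synthetic_oxyr_protein()
    cds = back_translate(protein)
    planted = [
        PlantedVariant(genome_id=f"nat-{i + 1:04d}",
                       substitution=MutationRecord.parse(s),
                       synonymous_extras=i % 3)
        for i, s in enumerate(oxyr.natural_isolate_substitutions())
    ]
    collection, truth = simulate_alleles(
        protein, cds, n_background=params["n_background_genomes"],
        planted=planted, duplicate_rate=params["duplicate_rate"], seed=seed,
    )
    collection.to_fasta(out / "alleles.fasta")
    truth.to_csv(out / "alleles_truth.tsv", sep="\t", index=False)
    with open(out / "reference.fasta", "w") as fh:
        fh.write(">oxyr_reference_synthetic\n")
        for i in range(0, len(cds), 70):
            fh.write(cds[i : i + 70] + "\n")
    (out / "refset.json").write_text(
        json.dumps(oxyr.constitutive_reference_positions(), indent=2)
    )
    produced += [out / "alleles.fasta", out / "alleles_truth.tsv",
                 out / "reference.fasta", out / "refset.json"]

    # structures: toy conformers on the OxyR coordinate system
    features = oxyr.feature_annotation()
    displacement = {p: np.array([2.0, 0.0, 0.0]) for p in range(199, 217)}
    reduced, oxidized, _ = simulate_structure(
        n_residues=oxyr.OXYR_LENGTH, feature_map=features.features,
        displacement=displacement, seed=seed,
    )
    write_pdb(reduced, out / "reduced.pdb")
    write_pdb(oxidized, out / "oxidized.pdb")
    feat_json = {
        "features": {str(k): v for k, v in features.features.items()},
        "regions": {k: list(v) for k, v in features.regions.items()},
    }
    (out / "features.json").write_text(json.dumps(feat_json, indent=2))
    muts = pd.DataFrame(
        [{"wt": m.wt_aa, "pos": m.position, "var": m.var_aa, "origin": m.origin}
         for m in oxyr.ale_mutations()]
    )
    muts.to_csv(out / "mutations.tsv", sep="\t", index=False)
    produced += [out / "reduced.pdb", out / "oxidized.pdb",
                 out / "features.json", out / "mutations.tsv"]

    # proteome abundances: defense genes with ahpC/ahpF/katG most abundant
    regulon = sorted(demo_modulons()[0].member_genes)
    rng = np.random.default_rng(seed)
    phi = {g: float(v) for g, v in zip(regulon, rng.uniform(1e-5, 5e-4, len(regulon)))}
    phi["ahpC"], phi["ahpF"], phi["katG"] = 0.02, 0.012, 0.008
    pd.DataFrame({"gene": list(phi), "phi_ref": list(phi.values())}).to_csv(
        out / "abundance.tsv", sep="\t", index=False
    )
    produced.append(out / "abundance.tsv")

    # growth curves: dose-dependent lag extension; GMOS dies at the top dose
    for offset, (strain, lags) in enumerate([
        ("WT", {0.0: 1.0, 1.0: 1.6, 2.5: 2.4, 5.0: 3.6}),
        ("GMOS", {0.0: 1.0, 1.0: 2.0, 2.5: 3.4, 5.0: None}),
        ("iron-evolved", {0.0: 1.0, 1.0: 1.05, 2.5: 1.1, 5.0: 1.15}),
    ]):
        gc = simulate_growth_curves(
            mu_max=0.9, lag_by_dose=lags, seed=seed + 101 * (offset + 1),
            strain=strain,
        )
        mode = "w" if strain == "WT" else "a"
        gc.data.to_csv(out / "growth.tsv", sep="\t", index=False, mode=mode,
                       header=(mode == "w"))
    produced.append(out / "growth.tsv")
    return produced


def stage_ica(ctx: StageContext) -> list[Path]:
    out = ctx.out_dir
    expr, meta = _require(ctx, "expression.tsv", "expression_meta.tsv")
    em = ExpressionMatrix.from_tsv(expr, meta)
    Xc = center_to_reference(em)
    p = ctx.config.ica
    model = robust_ica(Xc, n_components=p["n_components"],
                       n_restarts=p["n_restarts"],
                       min_recurrence=p["min_recurrence"], seed=ctx.config.seed)
    model.S.to_csv(out / "ica_S.tsv", sep="\t", index_label="gene_id")
    model.A.to_csv(out / "ica_A.tsv", sep="\t", index_label="component")
    memberships = []
    regulons = demo_known_regulons()
    for comp in model.S.columns:
        im = define_membership(model.S[comp])
        match = match_regulon(im.members, regulons, universe_size=len(model.S))
        memberships.append(
            {"component": comp, "regulator": match.regulator,
             "p": match.p_value, "robustness": float(model.robustness[comp]),
             "genes": sorted(im.members)}
        )
    (out / "imodulons.json").write_text(json.dumps(memberships, indent=2))
    return [out / "ica_S.tsv", out / "ica_A.tsv", out / "imodulons.json"]


def stage_activities(ctx: StageContext) -> list[Path]:
    out = ctx.out_dir
    a_path, meta_path = _require(ctx, "ica_A.tsv", "expression_meta.tsv")
    A = pd.read_csv(a_path, sep="\t", index_col="component")
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    grouping = meta["condition"]
    frames = []
    for comp in A.index:
        summary = activity_summary(A, comp, grouping).reset_index()
        summary.insert(0, "component", comp)
        frames.append(summary)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "activity_summary.tsv", sep="\t", index=False)
    return [out / "activity_summary.tsv"]


def stage_proximity(ctx: StageContext) -> list[Path]:
    out = ctx.out_dir
    oxi_p, red_p, feat_p, mut_p = _require(
        ctx, "oxidized.pdb", "reduced.pdb", "features.json", "mutations.tsv"
    )
    oxidized = read_structure(oxi_p, conformer="oxidized")
    reduced = read_structure(red_p, conformer="reduced")
    feat_raw = json.loads(feat_p.read_text())
    from .structure_proximity import FeatureAnnotation

    features = FeatureAnnotation(
        features={int(k): v for k, v in feat_raw["features"].items()},
        regions={k: tuple(v) for k, v in feat_raw["regions"].items()},
    )
    muts_df = pd.read_csv(mut_p, sep="\t")
    mutations = [
        MutationRecord(wt_aa=r.wt, position=int(r.pos), var_aa=r.var,
                       origin=r.origin)
        for r in muts_df.itertuples()
    ]
    p = ctx.config.proximity
    matrix = proximity_matrix(oxidized, reduced, mutations, features,
                              metric=p["metric"])
    matrix.to_csv(out / "proximity.tsv", sep="\t", index=False)
    classes = []
    for mut in mutations:
        row = matrix[matrix["mutation"] == str(mut)]
        label, evidence = classify_mutation(mut, row, features,
                                            contact_cutoff=p["cutoff"])
        classes.append({"mutation": str(mut), "origin": mut.origin,
                        "label": label, "evidence": evidence})
    (out / "classification.json").write_text(json.dumps(classes, indent=2))
    return [out / "proximity.tsv", out / "classification.json"]


def stage_scan(ctx: StageContext) -> list[Path]:
    out = ctx.out_dir
    coll_p, ref_p, refset_p = _require(
        ctx, "alleles.fasta", "reference.fasta", "refset.json"
    )
    collection = AlleleCollection.from_fasta(coll_p)
    reference = AlleleCollection.from_fasta(ref_p)
    from Bio.Seq import Seq

    ref_protein = str(Seq(reference.records[0][1]).translate(table=11)).rstrip("*")
    refset = ConstitutiveReferenceSet(entries=json.loads(refset_p.read_text()))
    dedup = translate_and_dedup(collection)
    p = ctx.config.scan
    calls = {}
    for rep, members in dedup.protein_groups.items():
        result = call_substitutions(dedup.proteins[rep], ref_protein,
                                    min_identity=p["min_identity"])
        for gid in members:
            calls[gid] = result.substitutions
    screen = screen_constitutive(calls, refset, rule=p["rule"])
    screen.rows.to_csv(out / "screen.tsv", sep="\t", index=False)
    counts = dict(dedup.counts)
    counts.update(screen.counts)
    (out / "screen_counts.json").write_text(json.dumps(counts, indent=2))
    return [out / "screen.tsv", out / "screen_counts.json"]


def stage_cost(ctx: StageContext) -> list[Path]:
    out = ctx.out_dir
    (ab_p,) = _require(ctx, "abundance.tsv")
    ab = pd.read_csv(ab_p, sep="\t")
    phi = dict(zip(ab["gene"], ab["phi_ref"]))
    model = ProteomeCostModel(mu0=1.0, Phi=1.0, phi_ref=phi, alpha=1.0)
    f = float(ctx.config.cost["fold_change"])
    report = regulon_cost(model, {g: f for g in phi})
    report.per_gene.to_csv(out / "cost_report.tsv", sep="\t", index=False)
    (out / "cost_summary.json").write_text(
        json.dumps(
            {"relative_growth_rate": report.relative_growth_rate,
             "fold_change": f, "ranking": report.ranking[:5]},
            indent=2,
        )
    )
    return [out / "cost_report.tsv", out / "cost_summary.json"]


def stage_lag(ctx: StageContext) -> list[Path]:
    out = ctx.out_dir
    (growth_p,) = _require(ctx, "growth.tsv")
    data = pd.read_csv(growth_p, sep="\t")
    p = ctx.config.lag
    table = dose_response_table(data, method=p["method"],
                                delta_min=p["delta_min"])
    table.to_csv(out / "dose_response.tsv", sep="\t", index=False)
    return [out / "dose_response.tsv"]
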