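"""End-to-end pipeline: simulate -> mine -> annotate -> pcr -> classify ->
tree -> rates -> ht, as one reproducible run with a JSON config and a
machine-readable manifest.

Each stage reads and writes plain-text artifacts (FASTA, GFF3, TSV, Newick,
JSON) in the run directory, so partial reruns can resume from existing
stage outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann_mod
from . import families as fam_mod
from . import io as io_mod
from . import phylo, rates, search, synthetic

STAGE_ORDER = ("simulate", "mine", "annotate", "pcr", "classify", "tree",
               "rates", "ht")


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``default_config``)."""

    outdir: str
    seed: int = 1
    stages: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    mine: dict = field(default_factory=dict)
    annotate: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    tree: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    ht: dict = field(default_factory=dict)
    resume: bool = True

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = io_mod.read_json(path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config requires 'outdir'")
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def default_config(outdir: str, seed: int = 1,
                   background_length: int = 2_000_000) -> RunConfig:
    """The bundled demo scene: 2 Mb genome, 5 families x 6 copies."""
    return RunConfig(
        outdir=outdir,
        seed=seed,
        simulate={"background_length": background_length, "gc": 0.5,
                  "n_families": 5, "copy_number": 6,
                  "within_divergence": 0.03, "decay_fraction": 0.2},
    )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def truth_to_tsv(copies: list[synthetic.PlantedCopy], path) -> None:
    rows = [{
        "copy_id": c.copy_id, "family": c.family, "start": c.start,
        "end": c.end, "strand": c.strand, "intact": int(c.intact),
        "truncated_end": c.truncated_end or "", "tsd": c.tsd or "",
        "cassette_intact": int(c.cassette_intact),
    } for c in copies]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def loci_to_tsv(loci: list[search.SearchLocus], path) -> None:
    rows = []
    for i, locus in enumerate(loci):
        best = locus.best_hit
        rows.append({
            "locus_id": f"L{i + 1:03d}", "seq_id": locus.source_id,
            "start": locus.start, "end": locus.end, "strand": locus.strand,
            "score": round(best.score, 2),
            "coverage": round(best.coverage, 3),
            "clade": best.label or "",
            "identity": round(best.identity, 3) if best.identity else "",
            "translation": best.translation,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def loci_from_tsv(path) -> list[search.SearchLocus]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    loci = []
    for row in df.itertuples():
        hit = search.DomainHit(
            source_id=row.seq_id, frame=0, aa_start=0,
            aa_end=len(row.translation), nt_start=row.start, nt_end=row.end,
            strand=row.strand, score=float(row.score),
            coverage=float(row.coverage), translation=row.translation,
            label=row.clade or None)
        loci.append(search.SearchLocus(row.seq_id, int(row.start),
                                       int(row.end), row.strand, [hit]))
    return loci


def annotations_to_tsv(annotations: list[ann_mod.ElementAnnotation],
                       path) -> None:
    rows = []
    for i, a in enumerate(annotations):
        rows.append({
            "element_id": f"E{i + 1:03d}", "seq_id": a.seq_id,
            "start": a.element[0] if a.element else "",
            "end": a.element[1] if a.element else "",
            "strand": a.strand, "length": a.length or "",
            "ltr_identity": round(a.ltr_identity, 4) if a.ltr_identity else "",
            "ends_canonical": int(a.ltr_pair.ends_canonical) if a.ltr_pair else "",
            "tsd": a.tsd or "", "n_orfs": len(a.orfs),
            "domain_order": "-".join(a.domain_order),
            "cchc": int(a.cchc_present),
            "classification": a.classification,
            "partial": int(a.partial), "clade": a.label or "",
            "rt_int_protein": a.rt_int_protein,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_mod.write_json(config.__dict__, outdir / "config.json")
    manifest: dict = {"stages": {}, "seed": config.seed,
                      "outdir": str(outdir)}

    paths = {
        "genome": outdir / "genome.fasta",
        "truth_gff": outdir / "truth.gff3",
        "truth_tsv": outdir / "truth.tsv",
        "loci": outdir / "loci.tsv",
        "annotations_gff": outdir / "annotations.gff3",
        "elements": outdir / "elements.tsv",
        "pcr": outdir / "pcr_products.tsv",
        "families": outdir / "families.tsv",
        "membership": outdir / "membership.tsv",
        "tree": outdir / "elements.nwk",
        "clades": outdir / "clades.tsv",
        "rates": outdir / "rate_table.tsv",
        "ht": outdir / "ht_report.tsv",
    }

    def stage(name: str, outputs: list[Path], fn) -> None:
        if not config.enabled(name):
            manifest["stages"][name] = {"status": "disabled"}
            return
        if config.resume and outputs and all(p.exists() for p in outputs):
            manifest["stages"][name] = {"status": "resumed",
                                        "outputs": [str(p) for p in outputs]}
            return
        t0 = time.time()
        try:
            fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            io_mod.write_json(manifest, outdir / "manifest.json")
            raise StageFailure(name, exc) from exc
        manifest["stages"][name] = {
            "status": "ok", "wall_time_s": round(time.time() - t0, 2),
            "outputs": [str(p) for p in outputs],
        }

    def do_simulate():
        sim = dict(config.simulate)
        bg = sim.pop("background_length", 2_000_000)
        gc = sim.pop("gc", 0.5)
        genome, copies = synthetic.plant_elements(
            bg, gc, synthetic.demo_family_specs(**sim), config.seed)
        io_mod.write_fasta([genome], paths["genome"])
        feats = [f for c in copies for f in c.features]
        io_mod.write_gff3(feats, paths["truth_gff"])
        truth_to_tsv(copies, paths["truth_tsv"])

    stage("simulate", [paths["genome"], paths["truth_gff"],
                       paths["truth_tsv"]], do_simulate)

    def do_mine():
        genome = io_mod.read_fasta(paths["genome"])
        profile = search.build_profile(
            synthetic.rt_int_seed_alignment(),
            threshold=config.mine.get("threshold"))
        panel = synthetic.reference_panel()
        loci = search.mine_genome(
            genome, profile, panel,
            min_identity=config.mine.get("min_identity", 0.25),
            max_gap_nt=config.mine.get("max_gap_nt", 1000))
        loci_to_tsv(loci, paths["loci"])

    stage("mine", [paths["loci"]], do_mine)

    def do_annotate():
        genome = io_mod.read_fasta(paths["genome"])[0]
        loci = loci_from_tsv(paths["loci"])
        profiles = ann_mod.default_domain_profiles()
        trnas = synthetic.trna_panel()
        annotations = [
            ann_mod.annotate_element(locus, genome, profiles, trnas,
                                     flank=config.annotate.get("flank", 15000))
            for locus in loci
        ]
        feats = [f for a in annotations for f in ann_mod.annotation_features(a)]
        io_mod.write_gff3(feats, paths["annotations_gff"])
        annotations_to_tsv(annotations, paths["elements"])

    stage("annotate", [paths["annotations_gff"], paths["elements"]],
          do_annotate)

    def do_pcr():
        genome = io_mod.read_fasta(paths["genome"])[0]
        products = ann_mod.in_silico_pcr(genome, ann_mod.gyrt1_ty3a_pair())
        rows = [{"seq_id": f.seq_id, "start": f.start, "end": f.end,
                 "strand": f.strand, "length": f.attributes["length"]}
                for f in products]
        pd.DataFrame(rows, columns=["seq_id", "start", "end", "strand",
                                    "length"]).to_csv(
            paths["pcr"], sep="\t", index=False)

    stage("pcr", [paths["pcr"]], do_pcr)

    def do_classify():
        genome = io_mod.read_fasta(paths["genome"])[0]
        elements = pd.read_csv(paths["elements"], sep="\t",
                               keep_default_na=False)
        proteins = {row.element_id: row.rt_int_protein
                    for row in elements.itertuples() if row.rt_int_protein}
        fams = fam_mod.cluster_families(
            proteins, threshold=config.classify.get("threshold", 0.90))
        element_nt = {}
        for row in elements.itertuples():
            if row.start != "" and row.end != "":
                element_nt[row.element_id] = genome.residues[
                    int(row.start):int(row.end)]
            else:
                element_nt[row.element_id] = ""
        usable = {fam.representative_id: element_nt.get(fam.representative_id, "")
                  for fam in fams}
        fam_mod.summarize_families(
            [f for f in fams if usable[f.representative_id]],
            {k: v for k, v in usable.items() if v}, genome)
        pd.DataFrame([{
            "family": f.name, "size": len(f.member_ids),
            "representative": f.representative_id,
            "mean_identity": round(f.mean_within_identity, 4),
            "copy_number": f.copy_number,
            "genome_fraction": round(f.genome_fraction, 5),
        } for f in fams]).to_csv(paths["families"], sep="\t", index=False)
        pd.DataFrame([
            {"element_id": mid, "family": f.name}
            for f in fams for mid in f.member_ids
        ]).to_csv(paths["membership"], sep="\t", index=False)

    stage("classify", [paths["families"], paths["membership"]], do_classify)

    def do_tree():
        elements = pd.read_csv(paths["elements"], sep="\t",
                               keep_default_na=False)
        membership = pd.read_csv(paths["membership"], sep="\t")
        reps = pd.read_csv(paths["families"], sep="\t")
        panel = synthetic.reference_panel()
        seqs = [io_mod.SequenceRecord(r.id, r.residues, io_mod.AMINO_ACID)
                for r in panel]
        by_el = {row.element_id: row.rt_int_protein
                 for row in elements.itertuples()}
        for row in reps.itertuples():
            prot = by_el.get(row.representative, "")
            if prot:
                seqs.append(io_mod.SequenceRecord(
                    f"{row.family}", prot, io_mod.AMINO_ACID))
        aln = phylo.progressive_msa(seqs)
        tree = phylo.bootstrap(aln, n=config.tree.get("bootstrap", 100),
                               seed=config.seed,
                               model=config.tree.get("model", "poisson"))
        io_mod.write_newick(tree, paths["tree"])
        ref_labels = {r.id: r.id for r in panel}
        assignments = phylo.assign_clades(
            tree, ref_labels, support_min=config.tree.get("support_min", 50))
        pd.DataFrame([{
            "query": a.query_id, "clade": a.clade,
            "support": a.support if a.support is not None else "",
        } for a in assignments]).to_csv(paths["clades"], sep="\t", index=False)

    stage("tree", [paths["tree"], paths["clades"]], do_tree)

    def do_rates():
        table = rates.recompute_reference_rates()
        table.to_csv(paths["rates"], sep="\t", index=False)

    stage("rates", [paths["rates"]], do_rates)

    def do_ht():
        report = demo_ht_report()
        report.to_frame().to_csv(paths["ht"], sep="\t", index=False)

    stage("ht", [paths["ht"]], do_ht)

    io_mod.write_json(manifest, outdir / "manifest.json")
    return manifest


def demo_ht_scenario() -> dict:
    """The interkingdom HT test case built from the bundled divergence table.

    Host tree: fungi (basidiomycetes, chytrids) vs plants (mosses,
    Selaginella, ferns, seed plants, algae); element tree groups fungal and
    non-seed-plant elements with high support; element rates are the
    cross-kingdom RT-Int rows, gene rates the cross-kingdom Pho88/uapA rows.
    """
    host_tree = phylo.Tree.from_newick(
        "(((moss:1,selaginella:1):1,(fern:1,seed_plant:1):1):1,"
        "alga:2,(basidiomycete:1,chytrid:1):2);")
    element_tree = phylo.Tree.from_newick(
        "(((Tcn1_cneo:1,PpatensLTR1:1)90:1,SM-Tcn1:1)95:1,"
        "Tekay_maize:2,(Galadriel_tomato:1,Reina_maize:1)88:1);")
    leaf_to_host = {
        "Tcn1_cneo": "basidiomycete", "PpatensLTR1": "moss",
        "SM-Tcn1": "selaginella", "Tekay_maize": "seed_plant",
        "Galadriel_tomato": "seed_plant", "Reina_maize": "seed_plant",
    }
    presence = {"moss": True, "selaginella": True, "basidiomycete": True,
                "chytrid": True, "fern": False, "seed_plant": False,
                "alga": False}
    table = rates.recompute_reference_rates()
    cross = table[(table.group_a.isin(["Plants", "Fungi"]))
                  & (table.group_b.isin(["Plants", "Fungi"]))]
    te_rates = [r / rates.RATE_SCALE for r in
                cross[cross.section == "Tcn1"].computed_rate_1e9]
    gene_rates = [r / rates.RATE_SCALE for r in
                  cross[cross.section.isin(["Pho88", "uapA"])].computed_rate_1e9]
    return {
        "element_tree": element_tree, "host_tree": host_tree,
        "leaf_to_host": leaf_to_host, "presence": presence,
        "te_rates": te_rates, "gene_rates": gene_rates,
    }


def demo_ht_report() -> rates.HTReport:
    sc = demo_ht_scenario()
    return rates.ht_report("Tcn1-like", sc["element_tree"], sc["host_tree"],
                           sc["leaf_to_host"], sc["presence"],
                           sc["te_rates"], sc["gene_rates"])
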