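"""End-to-end orchestration: simulate/load -> identify -> phylogeny ->
structure + motifs -> duplication -> synteny, with report tables.

Every stage logs its record counts so the conservation invariants
(scanned = accepted + rejected; assigned = accepted) can be audited from
logs alone.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import duplication_synteny as ds
from . import family_identify as fi
from . import phylo_classify as pc
from . import structure_motifs as sm
from . import synthetic_data as sd
from .io_formats import (GenomeBundle, SequenceRecord, newick_string, read_fasta,
                         read_gff3, write_fasta, write_gff3)

log = logging.getLogger("genefam")


@dataclass
class PipelineConfig:
    outdir: str = "genefam_out"
    seed: int = 1
    simulate: sd.SimConfig | None = None
    proteome_fasta: str | None = None
    genome_fasta: str | None = None
    gff3: str | None = None
    references_fasta: str | None = None      # labeled: ">id|A4"
    seed_alignment_fasta: str | None = None
    evalue: float = 1e-5
    bits_threshold: float = fi.DEFAULT_BIT_THRESHOLD
    replicates: int = 1000
    max_motifs: int = 15
    min_motif_width: int = 6
    max_motif_width: int = 50
    motif_floor: float = sm.DEFAULT_SITE_FLOOR
    min_anchors: int = ds.DEFAULT_MIN_ANCHORS
    max_gap: int = ds.DEFAULT_MAX_GAP
    tandem_max_intervening: int = ds.TANDEM_MAX_INTERVENING
    run_synteny: bool = True

    def __post_init__(self) -> None:
        if self.simulate is None and not (self.proteome_fasta and self.gff3):
            raise ValueError("config needs either a simulate block or real "
                             "proteome/gff3 inputs")
        for name in ("evalue", "bits_threshold", "replicates", "max_motifs"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw, simulate=sd.SimConfig(**sim) if sim is not None else None)
        return cfg

    def width_grid(self) -> list[int]:
        grid = [w for w in sm.DEFAULT_WIDTH_GRID
                if self.min_motif_width <= w <= self.max_motif_width]
        return grid or [self.min_motif_width]


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    accepted: set[str] = field(default_factory=set)
    subgroup_labels: dict[str, str] = field(default_factory=dict)
    duplicate_pairs: list = field(default_factory=list)
    tree_newick: str | None = None
    truth: sd.PlantedTruth | None = None
    bundle: GenomeBundle | None = None
    motifs: list = field(default_factory=list)
    structures: dict = field(default_factory=dict)
    ortholog_count: int | None = None
    expected_ortholog_count: int | None = None


def _parse_labeled_refs(records: list[SequenceRecord]) -> tuple[list[SequenceRecord], dict[str, str]]:
    """References encode the subgroup after the id: ``id|A4``."""
    refs, labels = [], {}
    for r in records:
        if "|" in r.id:
            rid, label = r.id.rsplit("|", 1)
        elif r.description:
            rid, label = r.id, r.description.split()[0]
        else:
            raise ValueError(f"reference {r.id} carries no subgroup label")
        refs.append(SequenceRecord(rid, r.residues, description=label))
        labels[rid] = label
    return refs, labels


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute every stage; artifacts land under ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(params={"seed": cfg.seed, "evalue": cfg.evalue,
                               "replicates": cfg.replicates})

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name}: {exc}") from exc
            report.timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.1fs", name, report.timings[name])
        return deco

    state: dict = {}

    # ---- simulate or load -------------------------------------------------
    @stage("input")
    def _input():
        if cfg.simulate is not None:
            bundle, truth, refs, seed_aln = sd.simulate_genome(cfg.simulate)
            state.update(bundle=bundle, truth=truth, refs=refs, seed_aln=seed_aln)
            report.truth, report.bundle = truth, bundle
            write_fasta([SequenceRecord(c, s) for c, s in bundle.chromosome_seqs.items()],
                        out / "genome.fasta")
            write_fasta(sorted(bundle.proteins.values(), key=lambda r: r.id),
                        out / "proteins.fasta")
            write_gff3(bundle.genes, out / "genes.gff3", bundle.chromosomes)
            write_fasta([SequenceRecord(f"{r.id}|{r.description}", r.residues)
                         for r in refs], out / "references.fasta")
            write_fasta(seed_aln, out / "seed_alignment.fasta")
            pd.DataFrame(
                [(g, sg) for g, sg in sorted(truth.family_members.items())],
                columns=["gene_id", "subgroup"],
            ).to_csv(out / "truth_family.tsv", sep="\t", index=False)
            pd.DataFrame(
                [(a, b, n) for (a, b), n in sorted(truth.tandem_pairs.items())],
                columns=["id_a", "id_b", "intervening"],
            ).to_csv(out / "truth_tandem.tsv", sep="\t", index=False)
        else:
            proteome = read_fasta(cfg.proteome_fasta)
            genes = read_gff3(cfg.gff3)
            chroms: dict[str, int] = {}
            for g in genes:
                chroms[g.chromosome] = max(chroms.get(g.chromosome, 0), g.span[1])
            gene_ids = {g.gene_id for g in genes}
            bundle = GenomeBundle(genome_id="input", chromosomes=chroms,
                                  genes=genes,
                                  proteins={r.id: r for r in proteome
                                            if r.id in gene_ids})
            refs = None
            if cfg.references_fasta:
                refs, _ = _parse_labeled_refs(read_fasta(cfg.references_fasta))
            seed_aln = (read_fasta(cfg.seed_alignment_fasta)
                        if cfg.seed_alignment_fasta else fi.packaged_seed_alignment())
            state.update(bundle=bundle, truth=None, refs=refs, seed_aln=seed_aln)
            report.bundle = bundle

    # ---- identify ---------------------------------------------------------
    @stage("identify")
    def _identify():
        bundle: GenomeBundle = state["bundle"]
        refs = state["refs"]
        if refs is None:
            raise ValueError("missing references input (labeled FASTA)")
        proteome = sorted(bundle.proteins.values(), key=lambda r: r.id)
        candidates = fi.candidate_search(refs, proteome, cfg.evalue)
        profile = fi.build_profile(state["seed_aln"])
        hits_by_protein = {}
        for pid in sorted(candidates):
            hits_by_protein[pid] = fi.scan_domain(bundle.proteins[pid], profile,
                                                  cfg.bits_threshold)
        accepted, v_and_e, v_only, rejected = fi.filter_dreb(hits_by_protein)
        assert len(accepted) + len(rejected) == len(hits_by_protein)
        rows = []
        for pid in sorted(hits_by_protein):
            hits = hits_by_protein[pid]
            status = ("accepted" if pid in accepted else rejected[pid])
            phys = fi.physchem(bundle.proteins[pid]) if pid in accepted else None
            h0 = hits[0] if hits else None
            rows.append({
                "gene_id": pid,
                "n_domains": len(hits),
                "domain_span": f"{h0.query_span[0]}-{h0.query_span[1]}" if h0 else "",
                "residue14": h0.residue14 if h0 else "",
                "residue19": h0.residue19 if h0 else "",
                "status": status,
                "length": phys.length if phys else "",
                "MW_Da": round(phys.mw, 2) if phys else "",
                "pI": round(phys.pi, 2) if phys else "",
            })
        table = pd.DataFrame(rows)
        table.to_csv(out / "identification.tsv", sep="\t", index=False)
        report.tables["identification"] = table
        report.counts.update(proteome=len(proteome), candidates=len(candidates),
                             scanned=len(hits_by_protein), accepted=len(accepted),
                             v_and_e=len(v_and_e), v_only=len(v_only),
                             rejected=len(rejected))
        report.accepted = accepted
        state.update(accepted=accepted, profile=profile)
        log.info("identify: %d scanned = %d accepted + %d rejected",
                 len(hits_by_protein), len(accepted), len(rejected))

    # ---- phylogeny + subgroups ---------------------------------------------
    @stage("phylo")
    def _phylo():
        bundle: GenomeBundle = state["bundle"]
        refs = state["refs"]
        accepted = sorted(state["accepted"])
        ref_labels = {r.id: r.description for r in refs}
        seqs = [bundle.proteins[a] for a in accepted] + list(refs)
        msa = pc.align_family(seqs)
        dm = pc.poisson_distance(msa)
        tree = pc.nj_tree(dm)
        supports = pc.bootstrap_supports(msa, cfg.replicates, seed=cfg.seed + 1)
        pc.attach_supports(tree, supports)
        assignment = pc.assign_subgroups(tree, ref_labels)
        assert set(assignment.labels) == set(accepted)
        report.subgroup_labels = assignment.labels
        report.tree_newick = newick_string(tree)
        (out / "tree.newick").write_text(report.tree_newick + "\n")
        table = pd.DataFrame(
            [(g, assignment.labels[g], assignment.method[g]) for g in accepted],
            columns=["gene_id", "subgroup", "method"])
        table.to_csv(out / "subgroups.tsv", sep="\t", index=False)
        counts = table["subgroup"].value_counts().sort_index()
        counts.rename("n_genes").to_csv(out / "subgroup_counts.tsv", sep="\t")
        report.tables["subgroups"] = table
        report.counts["assigned"] = len(assignment.labels)

    # ---- gene structure -----------------------------------------------------
    @stage("structure")
    def _structure():
        bundle: GenomeBundle = state["bundle"]
        rows = []
        for gid in sorted(state["accepted"]):
            st = sm.gene_structure(bundle.gene(gid))
            report.structures[gid] = st
            rows.append({"gene_id": gid, "n_exons": st.n_exons,
                         "n_introns": st.n_introns,
                         "intron_phases": ",".join(map(str, st.intron_phases))})
        table = pd.DataFrame(rows)
        table.to_csv(out / "structure.tsv", sep="\t", index=False)
        report.tables["structure"] = table

    # ---- motifs -------------------------------------------------------------
    @stage("motifs")
    def _motifs():
        bundle: GenomeBundle = state["bundle"]
        accepted = sorted(state["accepted"])
        proteins = [bundle.proteins[a] for a in accepted]
        motifs = sm.discover_motifs(proteins, widths=cfg.width_grid(),
                                    max_motifs=cfg.max_motifs, seed=cfg.seed + 2)
        report.motifs = motifs
        occurrences = []
        for m in motifs:
            for p in proteins:
                occ = sm.scan_motif(p, m, cfg.motif_floor)
                if occ is not None:
                    occurrences.append(occ)
        mt = pd.DataFrame([{"motif_id": m.motif_id, "width": m.width,
                            "consensus": m.consensus, "llr": round(m.llr, 3)}
                           for m in motifs])
        mt.to_csv(out / "motifs.tsv", sep="\t", index=False)
        st = pd.DataFrame([{"motif_id": o.motif_id, "gene_id": o.protein_id,
                            "offset": o.offset, "score": round(o.site_score, 3)}
                           for o in occurrences])
        st.to_csv(out / "motif_sites.tsv", sep="\t", index=False)
        pm = sm.presence_matrix(accepted, motifs, occurrences)
        pm.to_csv(out / "motif_presence.tsv", sep="\t")
        report.tables["motifs"] = mt
        report.tables["motif_sites"] = st
        report.counts["motifs"] = len(motifs)

    # ---- duplication --------------------------------------------------------
    @stage("duplication")
    def _duplication():
        bundle: GenomeBundle = state["bundle"]
        accepted = sorted(state["accepted"])
        tandem = ds.detect_tandem(accepted, bundle, cfg.tandem_max_intervening)
        proteome = sorted(bundle.proteins.values(), key=lambda r: r.id)
        pairs = ds.homolog_pairs(proteome, genome_a=bundle.genome_id,
                                 reciprocal_best=True)
        state["self_pairs"] = pairs
        blocks = ds.detect_collinear(bundle, bundle, pairs,
                                     cfg.min_anchors, cfg.max_gap)
        classified = ds.classify_duplicates(accepted, tandem, blocks)
        ds.annotate_pairs(classified, bundle)
        report.duplicate_pairs = classified
        table = pd.DataFrame([{
            "id_a": p.id_a, "id_b": p.id_b, "type": p.dup_type,
            "intervening": p.intervening_loci if p.intervening_loci is not None else "",
            "Ka": round(p.ka, 4) if p.ka is not None else "",
            "Ks": round(p.ks, 4) if p.ks is not None else "",
            "omega": round(p.omega, 4) if p.omega is not None else "",
            "T_MYA": round(p.t_mya, 2) if p.t_mya is not None else "",
        } for p in classified])
        table.to_csv(out / "duplication.tsv", sep="\t", index=False)
        report.tables["duplication"] = table
        report.counts["tandem_pairs"] = sum(p.dup_type == "tandem" for p in classified)
        report.counts["segmental_pairs"] = sum(p.dup_type == "segmental"
                                               for p in classified)

    # ---- cross-genome synteny ----------------------------------------------
    def _synteny():
        bundle: GenomeBundle = state["bundle"]
        truth = state["truth"]
        if truth is None:
            log.info("synteny: no second genome available; skipped")
            return
        bundle_b, expected, _shared = sd.simulate_ortholog_genome(
            bundle, truth, seed=cfg.seed + 3)
        prot_a = sorted(bundle.proteins.values(), key=lambda r: r.id)
        prot_b = sorted(bundle_b.proteins.values(), key=lambda r: r.id)
        # all significant pairs: reciprocal-best would drop recent tandem
        # duplicates whose best cross-genome hit is the partner's ortholog
        pairs = ds.homolog_pairs(prot_a, prot_b, genome_a=bundle.genome_id,
                                 genome_b=bundle_b.genome_id)
        blocks = ds.detect_collinear(bundle, bundle_b, pairs,
                                     cfg.min_anchors, cfg.max_gap)
        count = ds.ortholog_counts(blocks, state["accepted"])
        report.ortholog_count = count
        report.expected_ortholog_count = expected
        rows = [{"block_id": b.block_id, "chrom_a": b.chromosomes[0],
                 "chrom_b": b.chromosomes[1], "n_anchors": len(b.anchors),
                 "orientation": b.orientation} for b in blocks]
        pd.DataFrame(rows).to_csv(out / "synteny_blocks.tsv", sep="\t", index=False)
        pd.DataFrame([{"family_genes_with_orthologs": count,
                       "expected": expected}]).to_csv(
            out / "synteny_counts.tsv", sep="\t", index=False)
        report.counts["synteny_blocks"] = len(rows)
        report.counts["family_orthologs"] = count

    if cfg.run_synteny:
        stage("synteny")(_synteny)

    assert report.counts["accepted"] == report.counts["assigned"]
    pd.DataFrame([report.counts]).to_csv(out / "run_counts.tsv", sep="\t", index=False)
    return report
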