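import numpy as np
import pytest

from _oracles import polya_oracle, tsd_oracle
from lectinfam.duplication import TandemCluster, find_tandem_clusters
from lectinfam.genome_io import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    compute_gene_ranks,
)
from lectinfam.retrogene import (
    HomologyHit,
    call_retrogenes,
    detect_polyA,
    detect_tsd,
    find_retro_candidates,
    gene_flank_sequences,
    retro_tandem_expansion,
    reverse_complement,
)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def build_annotation(specs):
    """specs: (gene_id, chrom, start, end, n_exons)."""
    ann = GenomeAnnotation(species="sp")
    for gid, chrom, start, end, n_exons in specs:
        locus = Interval(chrom, start, end, "+")
        if n_exons == 1:
            exons = [locus]
        else:
            width = (end - start - 400 * (n_exons - 1)) // n_exons
            exons, pos = [], start
            for _ in range(n_exons):
                exons.append(Interval(chrom, pos, pos + width, "+"))
                pos += width + 400
            exons[-1] = Interval(chrom, exons[-1].start, end, "+")
        ann.add(GeneModel(gene_id=gid, species="sp", locus=locus, exons=exons))
    return ann


class TestCandidates:
    ANN = [
        ("single", "chr1", 10_000, 11_000, 1),
        ("parent2x", "chr1", 50_000, 53_000, 2),
        ("parent3x", "chr2", 50_000, 54_000, 3),
        ("othersingle", "chr2", 90_000, 91_000, 1),
    ]

    def test_coverage_below_threshold_rejected(self):
        ann = build_annotation(self.ANN)
        hits = [HomologyHit("single", "parent2x", 1e-20, 0.69, 90.0)]
        assert find_retro_candidates(ann, [s[0] for s in self.ANN], hits) == []

    def test_qualifying_pair_with_multiexon_parent(self):
        ann = build_annotation(self.ANN)
        hits = [HomologyHit("single", "parent2x", 1e-12, 0.80, 90.0)]
        (call,) = find_retro_candidates(ann, [s[0] for s in self.ANN], hits)
        assert (call.retrogene, call.parent) == ("single", "parent2x")

    def test_best_evalue_parent_chosen_order_invariant(self, rng):
        ann = build_annotation(self.ANN)
        hits = [
            HomologyHit("single", "parent2x", 1e-12, 0.8, 90.0),
            HomologyHit("single", "parent3x", 1e-30, 0.9, 95.0),
            HomologyHit("othersingle", "parent2x", 1e-3, 0.9, 80.0),  # e-value fails
        ]
        baseline = find_retro_candidates(ann, [s[0] for s in self.ANN], hits)
        assert [(c.retrogene, c.parent) for c in baseline] == [("single", "parent3x")]
        for _ in range(5):
            shuffled = [hits[i] for i in rng.permutation(len(hits))]
            again = find_retro_candidates(ann, [s[0] for s in self.ANN], shuffled)
            assert [(c.retrogene, c.parent) for c in again] == [
                (c.retrogene, c.parent) for c in baseline
            ]

    def test_multiexon_query_never_a_candidate(self):
        ann = build_annotation(self.ANN)
        hits = [HomologyHit("parent2x", "parent3x", 1e-40, 0.95, 90.0)]
        assert find_retro_candidates(ann, [s[0] for s in self.ANN], hits) == []


class TestPolyA:
    def test_pure_run_found(self):
        seq = "GCGCGCGCGC" + "A" * 10 + "GCGC"
        hit = detect_polyA(seq)
        assert (hit.start_offset, hit.run_length) == (10, 10)
        assert hit.adenine_fraction == 1.0

    def test_no_tract_in_repeats(self):
        assert detect_polyA("ACGT" * 50) is None

    def test_interrupted_run_within_purity(self):
        seq = "GGGGG" + "AAAAGAAAAA" + "GGGGG"
        hit = detect_polyA(seq, min_purity=0.8)
        assert hit.run_length == 10
        assert hit.adenine_fraction == pytest.approx(0.9)

    @pytest.mark.parametrize("trial", range(15))
    def test_agrees_with_exhaustive_substring_scan(self, trial):
        rng = np.random.default_rng(900 + trial)
        # A-enriched alphabet so hits actually occur
        seq = random_seq(rng, 500, alphabet="AACGT")
        hit = detect_polyA(seq, window=500)
        expected = polya_oracle(seq, 500, 8, 0.8)
        if expected is None:
            assert hit is None
        else:
            assert (hit.run_length, hit.adenine_fraction, hit.start_offset) == (
                pytest.approx(expected[0]),
                pytest.approx(expected[1]),
                expected[2],
            )


class TestTsd:
    def test_planted_repeat_found(self):
        up = "CCCCCCCCCC" + "GATCGA"
        down = "GATCGA" + "GGGGGGGGGG"
        hit = detect_tsd(up, down)
        assert hit.repeat == "GATCGA"
        assert hit.length == 6
        assert (hit.left_position, hit.right_position) == (0, 0)

    def test_random_flanks_agree_with_exhaustive_scan(self):
        for trial in range(15):
            rng = np.random.default_rng(1300 + trial)
            up, down = random_seq(rng, 500), random_seq(rng, 500)
            hit = detect_tsd(up, down, search_bp=100)
            expected = tsd_oracle(up, down, 4, 20, 100)
            if expected is None:
                assert hit is None
            else:
                assert (hit.length, hit.left_position, hit.right_position) == (
                    expected[0], expected[1], expected[2],
                )

    def test_tie_broken_by_boundary_proximity(self):
        # two copies of the repeat upstream; the one nearest the gene wins
        up = "CCCC" + "GATTACAA" + "CCCC" + "GATTACAA"
        down = "GATTACAA" + "GGGGGGGG"
        hit = detect_tsd(up, down)
        assert hit.left_position == 0
        assert hit.right_position == 0


class TestCallsAndTiers:
    def _genome(self, rng, tsd="GATTACA", polya=15, erode_tsd=False):
        """Flank windows use disjoint backgrounds (CT / GA dinucleotide
        repeats) so the planted TSD is the only shared >=4-mer; erosion
        then removes the only possible repeat instead of leaving chance
        k-mers behind."""
        chrom = random_seq(rng, 30_000)
        start, end = 10_000, 11_000
        seq = list(chrom)
        up_window = ("CT" * 60)[:120 - len(tsd)]
        up_window += tsd if not erode_tsd else "CT" * (len(tsd) // 2) + "C" * (len(tsd) % 2)
        seq[start - 120:start] = list(up_window)
        down_window = "A" * polya
        down_window += tsd if not erode_tsd else ("GA" * len(tsd))[:len(tsd)]
        down_window += ("GA" * 60)[:120 - len(down_window)]
        seq[end:end + 120] = list(down_window)
        ann = build_annotation(
            [("retro", "chr1", start, end, 1), ("par", "chr1", 20_000, 23_000, 2)]
        )
        calls = find_retro_candidates(
            ann, ["retro", "par"], [HomologyHit("retro", "par", 1e-30, 0.9, 95.0)]
        )
        return call_retrogenes(calls, ann, {"chr1": "".join(seq)})

    def test_intact_hallmarks_give_both_tier(self, rng):
        (call,) = self._genome(rng)
        assert call.tier == "+both"
        # the planted repeat may be chance-extended by flanking bases
        assert "GATTACA" in call.tsd.repeat
        assert call.polya.run_length >= 15

    def test_eroded_tsd_degrades_to_polya_tier(self, rng):
        (call,) = self._genome(rng, erode_tsd=True)
        assert call.tier == "+polyA"

    def test_minus_strand_flanks_are_reverse_complemented(self):
        chrom = "A" * 100 + "GGGG" + "C" * 50 + "TTTT" + "A" * 100
        locus = Interval("chr1", 104, 154, "-")
        gene = GeneModel(gene_id="g", species="sp", locus=locus, exons=[locus])
        up, down = gene_flank_sequences(gene, chrom, 30)
        # on the minus strand, upstream = revcomp of the right flank
        assert up == reverse_complement(chrom[154:184])
        assert down == reverse_complement(chrom[74:104])

    def test_specificity_no_calls_without_retro_plants(self, rng):
        """Decoy single-exon genes with sub-threshold homology stay uncalled."""
        from lectinfam.simulate import SimulationConfig, place_genes_on_genome
        from lectinfam.simulate import simulate_family_evolution, synthesize_homology_table
        from lectinfam.retrogene import read_homology_table

        config = SimulationConfig(
            seed=31,
            ancestral_sizes={"B_lectin": 3},
            birth_rates={"soybean": 4.0, "rice": 3.0, "arabidopsis": 2.0},
            p_retro=0.0,
            n_decoy_single_exon=100,
        )
        gen = np.random.default_rng(config.seed)
        families = simulate_family_evolution(config, gen)
        placed = place_genes_on_genome(families, "soybean", config, gen)
        table, lengths = synthesize_homology_table(families, placed, config, gen)
        ann = compute_gene_ranks(placed.annotation)
        hits = [
            HomologyHit(r.qseqid, r.sseqid, r.evalue,
                        (abs(r.qend - r.qstart) + 1) / lengths[r.qseqid], r.pident)
            for r in table.itertuples(index=False)
        ]
        lectins = [g.gene_id for f in families.values() for g in f.genes_of("soybean")]
        lectins += placed.decoy_genes
        assert find_retro_candidates(ann, lectins, hits) == []


class TestRetroTandem:
    def test_retro_seeding_a_cluster_reported_with_cluster(self):
        cluster = TandemCluster("c1", "B_lectin", "chr1",
                                ["retro", "x1", "x2", "x3"],
                                Interval("chr1", 0, 10_000))
        from lectinfam.retrogene import RetrogeneCall

        call = RetrogeneCall("retro", "par", 1e-30, 0.9)
        out = retro_tandem_expansion([call], [cluster])
        assert len(out) == 1
        assert len(out[0][1].members) == 4  # retrogene + three descendants

    def test_retro_outside_clusters_not_reported(self):
        from lectinfam.retrogene import RetrogeneCall

        call = RetrogeneCall("lonely", "par", 1e-30, 0.9)
        assert retro_tandem_expansion([call], []) == []

    def test_planted_retro_seeded_arrays_recovered(self, dataset):
        manifest = dataset["manifest"]
        retro = manifest[manifest["mechanism"] == "retro"]
        tandem = manifest[manifest["mechanism"] == "tandem"]
        seeded = set(retro["gene_id"]) & set(tandem["parent"])
        # deterministic dataset (fixed seed); vacuously true if no retrogene
        # happened to seed an array in this draw
        for species, bundle in dataset["species"].items():
            ann = compute_gene_ranks(bundle["placed"].annotation)
            fam = dict(zip(
                manifest[manifest["species"] == species]["gene_id"],
                manifest[manifest["species"] == species]["family"],
            ))
            clusters = find_tandem_clusters(fam, ann, max_bp=350_000)
            clustered = {m for c in clusters for m in c.members}
            for gid in seeded & set(fam):
                assert gid in clustered
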