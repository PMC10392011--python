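"""Annotation-stage behaviour: search symmetry and null rates, the intron
caps and length thresholds, decoy rejection, iterative recovery of
diverged genes, and the assembly QC rules."""

import numpy as np
import pytest

from olfrep._align import (
    AA_ALPHABET,
    random_protein,
    reverse_complement,
    reverse_translate,
)
from olfrep.annotate import (
    AssemblyStats,
    DraftModel,
    Hsp,
    chain_hsps,
    classify_family,
    compute_n50,
    extract_region,
    find_orf,
    iterate_annotation,
    qc_assembly,
    resolve_overlaps,
    translated_search,
)
from olfrep.simulate import RefProtein, make_references
from conftest import make_model


def _plant(protein, rng, background_len=30_000, at=10_000, strand="+"):
    """Random scaffold with one reverse-translated gene (guard stop 5')."""
    cds = "TAA" + reverse_translate(protein, rng) + "TAA"
    background = "".join("ACGT"[i] for i in rng.integers(0, 4, background_len))
    insert = cds if strand == "+" else reverse_complement(cds)
    return background[:at] + insert + background[at + len(insert):]


class TestTranslatedSearch:
    def test_exact_gene_yields_covering_hsp(self, references):
        rng = np.random.default_rng(0)
        query = references[0]
        genome = {"s1": _plant(query.seq, rng)}
        hsps = translated_search(genome, [query])
        best = max(hsps, key=lambda h: h.score)
        assert best.strand == "+"
        coverage = (best.query_end - best.query_start) / len(query.seq)
        assert coverage >= 0.95

    def test_reverse_complement_found_on_minus_strand_same_score(self, references):
        rng = np.random.default_rng(0)
        query = references[0]
        fwd = {"s1": _plant(query.seq, rng)}
        rev = {"s1": reverse_complement(fwd["s1"])}
        h_fwd = max(translated_search(fwd, [query]), key=lambda h: h.score)
        h_rev = max(translated_search(rev, [query]), key=lambda h: h.score)
        assert h_rev.strand == "-"
        assert h_rev.score == h_fwd.score
        L = len(fwd["s1"])
        assert (h_rev.target_start, h_rev.target_end) == (
            L - h_fwd.target_end, L - h_fwd.target_start
        )

    def test_random_scaffolds_produce_no_hits_at_threshold(self, references):
        """Empirical null: 1000 random scaffolds shorter than 3x the query
        give zero HSPs at the default score threshold."""
        rng = np.random.default_rng(123)
        query = references[0]  # 320 aa
        genome = {
            f"r{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 900))
            for i in range(1000)
        }
        assert translated_search(genome, [query], min_score=120) == []

    def test_lowering_min_score_never_shrinks_hsp_set(self, planted, references):
        genome, _ = planted
        sub = {"scaf1": genome["scaf1"]}
        strict = translated_search(sub, references, min_score=200)
        loose = translated_search(sub, references, min_score=120)
        assert set(strict) <= set(loose)

    def test_empty_genome_rejected(self, references):
        with pytest.raises(ValueError):
            translated_search({}, references)

    def test_non_protein_reference_rejected(self):
        bad = [RefProtein("x", "OR", None, "MKV1LLQ")]
        with pytest.raises(ValueError):
            translated_search({"s": "ACGT" * 100}, bad)


def _hsp(qid, start, end, score, qstart=0, qend=100, family="OR",
         scaffold="s", strand="+"):
    return Hsp(query_id=qid, query_family=family, scaffold=scaffold,
               target_start=start, target_end=end, strand=strand,
               query_start=qstart, query_end=qend, score=score, frame=0)


class TestResolveOverlaps:
    def test_disjoint_hsps_from_different_queries_kept(self):
        hsps = [_hsp("q1", 0, 300, 200), _hsp("q2", 1000, 1300, 150)]
        assert resolve_overlaps(hsps) == sorted(
            hsps, key=lambda h: h.target_start
        )

    def test_overlapping_lower_scoring_query_dropped(self):
        keep = _hsp("q1", 0, 300, 200)
        drop = _hsp("q2", 100, 400, 150)
        assert resolve_overlaps([keep, drop]) == [keep]

    def test_summed_score_decides_connected_component(self):
        # q1 chain 100+100 overlaps q2's single 150: q1 wins the component
        a = _hsp("q1", 0, 300, 100, qstart=0, qend=100)
        b = _hsp("q1", 600, 900, 100, qstart=100, qend=200)
        c = _hsp("q2", 200, 700, 150)
        assert resolve_overlaps([a, b, c]) == [a, b]

    def test_tie_broken_by_lexicographic_query_id(self):
        a = _hsp("q2", 0, 300, 150)
        b = _hsp("q1", 100, 400, 150)
        assert resolve_overlaps([a, b]) == [b]


class TestChaining:
    def test_single_hsp_single_exon_draft(self):
        drafts = chain_hsps([_hsp("q", 0, 300, 200)])
        assert len(drafts) == 1 and len(drafts[0].exons) == 1

    @pytest.mark.parametrize(
        "family,gap,n_drafts",
        [
            ("OR", 5_000, 1),      # within the 10 kb cap: one two-exon model
            ("OR", 12_000, 2),     # cap exceeded: split
            ("OR", 10_000, 1),     # boundary inclusive
            ("V2R", 25_000, 1),    # V2R cap is 30 kb
            ("V2R", 31_000, 2),
        ],
    )
    def test_intron_caps_by_family(self, family, gap, n_drafts):
        a = _hsp("q", 0, 300, 200, qstart=0, qend=100, family=family)
        b = _hsp("q", 300 + gap, 600 + gap, 200, qstart=100, qend=200,
                 family=family)
        assert len(chain_hsps([a, b])) == n_drafts

    def test_non_collinear_query_coordinates_not_chained(self):
        a = _hsp("q", 0, 300, 200, qstart=100, qend=200)
        b = _hsp("q", 5300, 5600, 200, qstart=0, qend=100)
        assert len(chain_hsps([a, b])) == 2


class TestRegionAndOrf:
    def test_flank_extension_and_clamping(self):
        genome = {"s": "A" * 100_000}
        d = DraftModel("q", "OR", "s", "+", ((10_000, 11_000),), ((0, 333),), 1.0)
        region, offset = extract_region(d, genome)
        assert (offset, offset + len(region)) == (7_000, 14_000)
        d2 = DraftModel("q", "OR", "s", "+", ((500, 1_500),), ((0, 333),), 1.0)
        region2, offset2 = extract_region(d2, genome)
        assert (offset2, offset2 + len(region2)) == (0, 4_500)

    def test_local_to_global_round_trip(self):
        rng = np.random.default_rng(5)
        genome = {"s": "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))}
        for _ in range(100):
            start = int(rng.integers(0, 45_000))
            end = start + int(rng.integers(100, 4_000))
            d = DraftModel("q", "OR", "s", "+", ((start, min(end, 50_000)),),
                           ((0, 100),), 1.0)
            region, offset = extract_region(d, genome)
            local = d.start - offset
            assert offset + local == d.start
            assert genome["s"][d.start] == region[local]

    @pytest.mark.parametrize(
        "family,length,status",
        [
            ("OR", 274, "rejected:length"),
            ("OR", 275, "intact"),
            ("V2R", 699, "rejected:length"),
            ("V2R", 700, "intact"),
        ],
    )
    def test_length_filter_boundaries(self, family, length, status):
        rng = np.random.default_rng(length)
        protein = random_protein(length, rng)
        region = _plant(protein, rng, background_len=6_000, at=2_000)
        start = 2_003
        end = start + 3 * length + 3
        d = DraftModel("q", family, "s", "+", ((start, end),),
                       ((0, length),), 1.0)
        result = find_orf(region, "+", d, family, offset=0)
        assert result.status == status
        if status == "intact":
            assert result.protein == protein

    def test_premature_stop_pseudogene_rejected(self):
        rng = np.random.default_rng(8)
        protein = random_protein(320, rng)
        cds = reverse_translate(protein, rng) + "TAA"
        stop_at = int(0.4 * 320)
        cds = cds[: 3 * stop_at] + "TAA" + cds[3 * stop_at + 3:]
        background = "".join("ACGT"[i] for i in rng.integers(0, 4, 4_000))
        region = background[:1000] + "TAA" + cds + background[1000 + len(cds) + 3:]
        d = DraftModel("q", "OR", "s", "+", ((1003, 1003 + 3 * stop_at),),
                       ((0, stop_at),), 1.0)
        result = find_orf(region, "+", d, "OR", offset=0)
        assert result.status == "rejected:length"


class TestClassification:
    def test_template_classified_to_own_family(self, references):
        for ref in references:
            if ref.family == "DECOY":
                continue
            family, subtype = classify_family(ref.seq, references)
            assert family == ref.family
            assert subtype == ref.subtype

    def test_decoy_protein_rejected_as_non_olf(self, references):
        decoy = next(r for r in references if r.family == "DECOY")
        family, reason = classify_family(decoy.seq, references)
        assert family is None and reason == "non_olf"

    def test_diverged_proteins_classified_correctly(self, references):
        """Templates mutated to 30% divergence keep their family label."""
        from olfrep._align import mutate_protein

        rng = np.random.default_rng(21)
        receptors = [r for r in references if r.family != "DECOY"]
        correct = 0
        trials = 100
        for i in range(trials):
            ref = receptors[int(rng.integers(len(receptors)))]
            mutant = mutate_protein(ref.seq, 0.30, rng)
            family, _ = classify_family(mutant, references)
            correct += family == ref.family
        assert correct >= 99

    def test_requires_decoys_in_database(self, references):
        receptors = [r for r in references if r.family != "DECOY"]
        with pytest.raises(ValueError):
            classify_family(receptors[0].seq, receptors)


class TestIteration:
    def test_two_hop_homolog_found_only_in_second_round(self):
        """A gene sharing no seed words with the initial reference is
        reached through an intermediate planted homolog."""
        refs = make_references(1, seed=2)
        template = next(r for r in refs if r.family == "OR")
        t = list(template.seq)
        a, b = list(t), list(t)
        alphabet = AA_ALPHABET
        for pos in range(3, len(t), 3):
            repl = alphabet[(alphabet.index(t[pos]) + 1) % len(alphabet)]
            b[pos] = repl
            if pos % 6 == 3:
                a[pos] = repl  # A carries half of B's mutations
        protein_a, protein_b = "".join(a), "".join(b)
        rng = np.random.default_rng(17)
        scaffold = _plant(protein_a, rng, background_len=120_000, at=10_000)
        cds_b = "TAA" + reverse_translate(protein_b, rng) + "TAA"
        scaffold = scaffold[:80_000] + cds_b + scaffold[80_000 + len(cds_b):]
        genome = {"s": scaffold}

        first_round, _ = iterate_annotation(genome, refs, max_iter=1)
        assert len(first_round) == 1  # only A is reachable directly
        models, info = iterate_annotation(genome, refs, max_iter=5)
        assert len(models) == 2
        assert info["added_per_iteration"][0] == 1
        assert info["added_per_iteration"][1] == 1

    def test_converged_annotation_is_a_fixed_point(self, planted, references,
                                                   annotated):
        genome, _ = planted
        models, info = annotated
        assert info["added_per_iteration"][-1] == 0
        again, _ = iterate_annotation(genome, references)
        assert [(m.scaffold, m.start, m.end) for m in again] == [
            (m.scaffold, m.start, m.end) for m in models
        ]

    def test_iteration_count_bounded(self, planted, references):
        genome, _ = planted
        _, info = iterate_annotation(genome, references, max_iter=2)
        assert info["iterations"] <= 2

    def test_strand_symmetry(self, references):
        """Annotating the reverse-complemented genome mirrors coordinates
        and preserves the recovered proteins."""
        rng = np.random.default_rng(31)
        template = next(r for r in references if r.family == "OR")
        scaffold = _plant(template.seq, rng, background_len=40_000, at=5_000)
        cds2 = "TAA" + reverse_translate(template.seq, rng) + "TAA"
        scaffold = scaffold[:25_000] + reverse_complement(cds2) + \
            scaffold[25_000 + len(cds2):]
        genome = {"s": scaffold}
        mirror = {"s": reverse_complement(scaffold)}
        fwd, _ = iterate_annotation(genome, references)
        rev, _ = iterate_annotation(mirror, references)
        L = len(scaffold)
        flipped = {(L - m.end, L - m.start, {"+": "-", "-": "+"}[m.strand],
                    m.protein) for m in rev}
        assert {(m.start, m.end, m.strand, m.protein) for m in fwd} == flipped


class TestAssemblyQc:
    def test_n50_examples(self):
        assert compute_n50([10]) == 10
        assert compute_n50([5, 4, 3, 2, 1]) == 4
        assert compute_n50([1, 1, 1, 1]) == 1

    def test_n50_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            lengths = rng.integers(1, 1000, size=int(rng.integers(1, 30)))
            total = lengths.sum()
            candidates = [
                x for x in lengths
                if sum(y for y in lengths if y >= x) >= total / 2
            ]
            assert compute_n50(lengths) == max(candidates)

    def test_n50_rejects_empty(self):
        with pytest.raises(ValueError):
            compute_n50([])

    def test_n50_ratio_boundary_is_inclusive(self):
        stats = AssemblyStats((10_000_000, 990_000_000), 0.95)
        # N50 10 Mb over 1 Gb: exactly the 10 Mb/Gb floor
        assert stats.n50 == 990_000_000  # single large scaffold dominates
        stats = AssemblyStats(tuple([10_000_000] * 100), 0.95)
        assert qc_assembly(stats, []).n50_ratio_pass

    def test_busco_tolerance_for_polypteriformes(self):
        stats = AssemblyStats((10**8,), 0.86, polypteriform=True)
        assert qc_assembly(stats, []).busco_pass
        stats = AssemblyStats((10**8,), 0.86, polypteriform=False)
        assert not qc_assembly(stats, []).busco_pass

    def test_or_scaffold_dispersion_rule(self):
        models20 = [make_model(f"m{i}", 0, 10, scaffold=f"s{i}")
                    for i in range(20)]
        stats = AssemblyStats((10**8,), 0.95)
        assert not qc_assembly(stats, models20).or_scaffold_dispersion_pass
        models30 = [make_model(f"m{i}", 0, 10, scaffold=f"s{i}")
                    for i in range(30)]
        stats_wgd = AssemblyStats((10**8,), 0.95, lineage_wgd=True)
        assert qc_assembly(stats_wgd, models30).or_scaffold_dispersion_pass
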