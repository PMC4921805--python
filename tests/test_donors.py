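import pytest

from ltrconv.clusters import SNPCluster, detect_clusters
from ltrconv.donors import (
    PSV,
    PSVSet,
    align_donor_ungapped,
    build_derived_tract,
    classify_conversion,
    filter_clusters_for_donor_search,
    identify_psvs,
    match_donors,
    tract_bounds,
)
from ltrconv.io_formats import Region, SequenceRecord
from ltrconv.phylogeny import BranchAssignment, polarize_and_assign
from ltrconv.published import CLUSTER_TABLE
from ltrconv.synthetic import SimConfig, simulate_dataset


def cluster(id=1, branch="b1", positions=(130, 145, 160), members=None):
    members = members or tuple(f"v{i}" for i in range(len(positions)))
    return SNPCluster(id=id, branch=branch, members=members, positions=tuple(positions))


class TestFilter:
    def test_span_two_excluded(self):
        short = cluster(positions=(100, 101))
        assert filter_clusters_for_donor_search([short]) == []

    def test_span_three_retained(self):
        keep = cluster(positions=(100, 102))
        assert filter_clusters_for_donor_search([keep]) == [keep]

    def test_empty_input(self):
        assert filter_clusters_for_donor_search([]) == []


def assignments_for(members, derived, ancestral="A"):
    return {
        m: BranchAssignment(m, ancestral, d, [("b1", "forward")])
        for m, d in zip(members, derived)
    }


class TestDerivedTract:
    def ref(self):
        return SequenceRecord("chrY:1-4", "AAAA", "chrY", 1, 4)

    def test_substitution_over_cluster_span(self):
        # span runs from the first to the last member (positions 2..4), with
        # the derived allele substituted at each member
        cl = cluster(positions=(2, 4), members=("m1", "m2"))
        tract = build_derived_tract(self.ref(), cl, assignments_for(("m1", "m2"), "TG"))
        assert tract == "TAG"

    def test_polarity_violation_rejected(self):
        cl = cluster(positions=(2, 4), members=("m1", "m2"))
        bad = assignments_for(("m1", "m2"), "AA")  # derived == ancestral
        with pytest.raises(ValueError, match="derived equals ancestral"):
            build_derived_tract(self.ref(), cl, bad)

    def test_member_outside_reference_rejected(self):
        cl = cluster(positions=(2, 9), members=("m1", "m2"))
        with pytest.raises(ValueError, match="outside"):
            build_derived_tract(self.ref(), cl, assignments_for(("m1", "m2"), "TG"))


class TestMatchDonors:
    def setup_method(self):
        self.ref = SequenceRecord("chrY:1-20", "A" * 20, "chrY", 1, 20)
        self.cl = cluster(positions=(5, 8), members=("m1", "m2"))
        self.assign = assignments_for(("m1", "m2"), "TG")
        self.tract = build_derived_tract(self.ref, self.cl, self.assign)  # TAAG

    def donor(self, seq, id="donorA:1-20", chrom="donorA"):
        return SequenceRecord(id, seq, chrom, 1, len(seq))

    def test_exact_donor_is_a_hit(self):
        donor = self.donor("A" * 4 + "TAAG" + "A" * 12)
        hits = match_donors(self.tract, self.cl, [donor], self.ref)
        assert len(hits) == 1 and hits[0].identity

    def test_single_mismatch_destroys_hit_at_every_position(self):
        base = "A" * 4 + "TAAG" + "A" * 12
        for i in range(4, 8):
            for sub in "ACGT":
                if sub == base[i]:
                    continue
                mutated = base[:i] + sub + base[i + 1 :]
                assert match_donors(self.tract, self.cl,
                                    [self.donor(mutated)], self.ref) == []

    def test_multiple_identical_donors_all_reported(self):
        d1 = self.donor("A" * 4 + "TAAG" + "A" * 12, id="d1:1-20", chrom="d1")
        d2 = self.donor("A" * 4 + "TAAG" + "A" * 12, id="d2:1-20", chrom="d2")
        hits = match_donors(self.tract, self.cl, [d1, d2], self.ref)
        assert {h.donor_id for h in hits} == {"d1:1-20", "d2:1-20"}

    def test_donor_not_covering_span_skipped(self):
        short = SequenceRecord("d3", "TA")
        assert match_donors(self.tract, self.cl, [short], self.ref,
                            donor_offsets={"d3": 4}) == []

    def test_sliding_aligner_finds_offset(self):
        acceptor = "ACGTACGTACGTACGT"
        donor = "TACGTAC"
        assert align_donor_ungapped(acceptor, donor) == 3


class TestTractBounds:
    def psvs(self, positions):
        return PSVSet(
            donor_id="d",
            psvs=tuple(PSV(p, "A", "G") for p in positions),
        )

    def test_definition_applied(self):
        cl = cluster(positions=(130, 160), members=("m1", "m2"))
        converted = "A" * 300  # retains acceptor base A at the flanking PSVs
        mn, mx = tract_bounds(cl, self.psvs([100, 200]), converted)
        assert (mn, mx) == (31, 99)

    def test_inclusive_mode(self):
        cl = cluster(positions=(130, 160), members=("m1", "m2"))
        mn, mx = tract_bounds(cl, self.psvs([100, 200]), "A" * 300, mode="inclusive")
        assert mx == 101

    def test_converted_psv_not_a_bound(self):
        # PSV at 120 carries the DONOR base on the converted chromosome, so
        # conversion crossed it; the next PSV out (at 90) bounds the tract
        cl = cluster(positions=(130, 160), members=("m1", "m2"))
        converted = list("A" * 300)
        converted[120 - 1] = "G"
        mn, mx = tract_bounds(cl, self.psvs([90, 120, 200]), "".join(converted))
        assert mx == 200 - 90 - 1

    def test_no_flanking_psv_means_unbounded(self):
        cl = cluster(positions=(130, 160), members=("m1", "m2"))
        mn, mx = tract_bounds(cl, self.psvs([200]), "A" * 300)
        assert mn == 31 and mx is None

    def test_min_never_exceeds_max(self):
        cl = cluster(positions=(130, 160), members=("m1", "m2"))
        mn, mx = tract_bounds(cl, self.psvs([129, 161]), "A" * 300)
        assert mn <= mx == 31  # PSVs immediately flanking: equality case


class TestClassify:
    def test_intra_ltr(self):
        element = Region("LTR 24", "chrY", 16708286, 16711000)
        assert classify_conversion("chrY", 16708816, 16710643, "chrY",
                                   acceptor_element=element) == "intra-LTR"

    def test_autosome_to_y(self):
        assert classify_conversion("chr10", 19239555, 19240773, "chrY") == "autosome-to-Y"

    def test_x_to_y(self):
        assert classify_conversion("chrX", 8419802, 8421096, "chrY") == "X-to-Y"

    def test_y_to_y_outside_element(self):
        element = Region("LTR 2", "chrY", 2866000, 2867600)
        assert classify_conversion("chrY", 3966976, 3968339, "chrY",
                                   acceptor_element=element) == "Y-to-Y"

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            classify_conversion("chrM9", 1, 10, "chrY")


class TestPublishedTractTable:
    def test_mean_of_defined_max_tracts(self):
        maxima = [r.max_tract for r in CLUSTER_TABLE if r.max_tract is not None]
        assert len(maxima) == 14
        assert round(sum(maxima) / len(maxima)) == 99

    def test_min_tract_extremes(self):
        minima = [r.min_tract for r in CLUSTER_TABLE if r.min_tract is not None]
        assert min(minima) == 3 and max(minima) == 86


class TestIdentifyPsvs:
    def test_round_trip_with_generator(self):
        from ltrconv.synthetic import generate_donor_library

        anc = "ACGT" * 50
        donors, psv_sets = generate_donor_library(anc, 3, 0.05, seed=8)
        ref = SequenceRecord(f"chrY:1-{len(anc)}", anc, "chrY", 1, len(anc))
        for donor in donors:
            found = identify_psvs(ref, donor)
            assert found.positions == psv_sets[donor.id].positions
            assert found.psvs == psv_sets[donor.id].psvs


def tip_paths(tree):
    """branch names on the root-to-tip path, per tip."""
    paths = {}

    def walk(node, acc):
        for child in node.children:
            branch_path = acc + [child.name]
            if child.is_tip:
                paths[child.name] = branch_path
            walk(child, branch_path)

    walk(tree.root, [])
    return paths


class TestSimulatedTractBounds:
    def test_true_tract_between_cluster_span_and_max_bound(self):
        # for a simulated conversion covering >= 2 PSVs that is the only
        # conversion on its carrier lineage, the true tract length always
        # lies within [detected cluster span, reported max_tract]
        checked = 0
        for seed in range(15):
            res = simulate_dataset(SimConfig(seed=seed, mut_rate=0.0, conv_rate=0.3))
            assignments = polarize_and_assign(res.variants, res.tree)
            pos = {v.name: v.pos for v in res.variants}
            events = [(a.variant, pos[a.variant], b)
                      for a in assignments for b, _ in a.events]
            detected = detect_clusters(events)
            paths = tip_paths(res.tree)
            conv_branches = [e.branch for e in res.truth.conversions]
            for cl_ in detected:
                matches = [
                    e for e in res.truth.conversions
                    if e.branch == cl_.branch and e.n_psvs_covered >= 2
                    and cl_.start <= e.end and e.start <= cl_.end
                ]
                if len(matches) != 1 or conv_branches.count(cl_.branch) != 1:
                    continue
                (event,) = matches
                carriers = [
                    t for t in res.tips
                    if event.branch in paths[t.id]
                    and sum(b in paths[t.id] for b in conv_branches) == 1
                ]
                if not carriers:
                    continue
                carrier = carriers[0]
                mn, mx = tract_bounds(cl_, res.psv_sets[event.donor_id], carrier)
                tract_len = event.end - event.start + 1
                assert mn <= tract_len
                if mx is not None:
                    assert tract_len <= mx
                checked += 1
        assert checked >= 5
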