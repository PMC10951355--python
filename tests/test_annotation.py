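import numpy as np
import pytest

from icdomain.genome_io import (
    BinScheme,
    GenomicInterval,
    LoopRecord,
    StateInterval,
    TSSRecord,
)
from icdomain.annotation import (
    annotate_bins,
    assign_states,
    breadth_at_tss,
    classify_elements,
    make_promoters,
)


def promoter_bases(tss, strand, up, down, genome_len):
    """Per-base oracle for promoter windows."""
    if strand == "+":
        lo, hi = tss - up, tss + down
    else:
        lo, hi = tss - down, tss + up
    return set(range(max(0, lo), min(hi, genome_len)))


class TestMakePromoters:
    def test_plus_strand_window_spans_upstream_to_downstream(self):
        recs = [TSSRecord("g", "chr1", 10_000, "+")]
        assert make_promoters(recs)["g"] == GenomicInterval("chr1", 7500, 10_100, "+")

    def test_minus_strand_window_is_mirrored(self):
        recs = [TSSRecord("g", "chr1", 10_000, "-")]
        assert make_promoters(recs)["g"] == GenomicInterval("chr1", 9900, 12_500, "-")

    def test_clipping_at_chromosome_start(self):
        recs = [TSSRecord("g", "chr1", 1000, "+")]
        assert make_promoters(recs)["g"] == GenomicInterval("chr1", 0, 1100, "+")

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            make_promoters([TSSRecord("g", "chr1", 1000, "+")], up=0, down=0)

    def test_unclipped_width_is_up_plus_down_on_both_strands(self):
        for strand in "+-":
            rec = TSSRecord("g", "chr1", 50_000, strand)
            iv = make_promoters([rec], up=2500, down=100)["g"]
            assert iv.width == 2600


class TestClassifyElements:
    PROM = {"g": GenomicInterval("chr1", 7500, 10_100)}

    def test_distant_peak_is_enhancer(self):
        peak = GenomicInterval("chr1", 20_000, 20_500)
        table = classify_elements([peak], self.PROM, window=1500)
        assert table.enhancers == [peak]

    def test_peak_within_window_absorbed_into_promoter_class(self):
        peak = GenomicInterval("chr1", 11_000, 11_400)
        table = classify_elements([peak], self.PROM, window=1500)
        assert table.enhancers == []

    def test_zero_window_abutting_peak_is_enhancer(self):
        peak = GenomicInterval("chr1", 10_100, 10_600)  # end-abuts the promoter
        table = classify_elements([peak], self.PROM, window=0)
        assert table.enhancers == [peak]

    def test_geometry_matches_per_base_oracle(self):
        """Random TSS/peak layouts on a 10 kb toy genome, both strands."""
        rng = np.random.default_rng(42)
        genome_len = 10_000
        for trial in range(20):
            up, down = 2500, 100
            window = int(rng.choice([0, 1500]))
            tss_list = [
                TSSRecord(
                    f"g{j}",
                    "chr1",
                    int(rng.integers(0, genome_len - 1)),
                    str(rng.choice(["+", "-"])),
                )
                for j in range(rng.integers(1, 4))
            ]
            promoters = make_promoters(
                tss_list, up=up, down=down, chrom_sizes={"chr1": genome_len}
            )
            base_sets = {
                r.gene_id: promoter_bases(r.tss, r.strand, up, down, genome_len)
                for r in tss_list
            }
            for gene, iv in promoters.items():
                assert set(range(iv.start, iv.end)) == base_sets[gene]
            peaks = []
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(0, genome_len - 100))
                peaks.append(GenomicInterval("chr1", s, s + int(rng.integers(50, 500))))
            table = classify_elements(peaks, promoters, window=window)
            all_prom_bases = set().union(*base_sets.values())
            for peak in peaks:
                ext = set(range(max(0, peak.start - window), peak.end + window))
                is_enh_oracle = not (ext & all_prom_bases)
                assert (peak in table.enhancers) == is_enh_oracle


SCHEME = BinScheme(bin_size=1000, chrom_sizes={"chr1": 10_000})


def _loop(k1, k2, count=1, q=0.001):
    return LoopRecord(
        SCHEME.bin_interval(("chr1", k1)), SCHEME.bin_interval(("chr1", k2)), count, q
    )


class TestAnnotateBins:
    def test_promoter_precedence_over_enhancer(self):
        from icdomain.annotation import ElementTable

        elements = ElementTable(
            promoters={"gA": GenomicInterval("chr1", 1200, 1500)},
            enhancers=[
                GenomicInterval("chr1", 1600, 1800),
                GenomicInterval("chr1", 1850, 1950),
            ],
        )
        annotation = annotate_bins(SCHEME, [_loop(1, 2)], elements)
        assert annotation[("chr1", 1)].element_class == "P"
        assert annotation[("chr1", 1)].gene_ids == {"gA"}

    def test_unannotated_bin_is_other(self):
        from icdomain.annotation import ElementTable

        annotation = annotate_bins(
            SCHEME, [_loop(1, 2)], ElementTable(promoters={}, enhancers=[])
        )
        assert annotation[("chr1", 2)].element_class == "other"

    def test_bin_collects_all_overlapping_promoter_genes(self):
        from icdomain.annotation import ElementTable

        elements = ElementTable(
            promoters={
                "gA": GenomicInterval("chr1", 1100, 1300),
                "gB": GenomicInterval("chr1", 1700, 1900),
            },
            enhancers=[],
        )
        annotation = annotate_bins(SCHEME, [_loop(1, 3)], elements)
        assert annotation[("chr1", 1)].gene_ids == {"gA", "gB"}

    def test_only_loop_bins_annotated_and_matches_per_base_oracle(self):
        """Brute-force per-base overlap oracle on a small random layout."""
        from icdomain.annotation import ElementTable

        rng = np.random.default_rng(7)
        for _ in range(10):
            promoters = {}
            for j in range(rng.integers(1, 4)):
                s = int(rng.integers(0, 9500))
                promoters[f"g{j}"] = GenomicInterval("chr1", s, s + int(rng.integers(50, 400)))
            enhancers = []
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(0, 9500))
                enhancers.append(GenomicInterval("chr1", s, s + int(rng.integers(50, 400))))
            loops = [_loop(*sorted(rng.choice(10, size=2, replace=False)))]
            annotation = annotate_bins(
                SCHEME, loops, ElementTable(promoters=promoters, enhancers=enhancers)
            )
            loop_bins = {("chr1", int(k)) for lp in loops for k in
                         (lp.bin1.start // 1000, lp.bin2.start // 1000)}
            assert set(annotation.bins) == loop_bins
            for bin_id, info in annotation.bins.items():
                bin_bases = set(range(bin_id[1] * 1000, bin_id[1] * 1000 + 1000))
                genes = {
                    g for g, iv in promoters.items()
                    if bin_bases & set(range(iv.start, iv.end))
                }
                assert info.gene_ids == genes
                enh_hit = any(
                    bin_bases & set(range(iv.start, iv.end)) for iv in enhancers
                )
                expected = "P" if genes else ("E" if enh_hit else "other")
                assert info.element_class == expected


class TestAssignStates:
    def _annotation(self, loops):
        from icdomain.annotation import ElementTable

        return annotate_bins(SCHEME, loops, ElementTable(promoters={}, enhancers=[]))

    def test_superenhancer_outranks_heterochromatin(self):
        annotation = self._annotation([_loop(1, 2)])
        states = [StateInterval(GenomicInterval("chr1", 1000, 2000), "Heterochromatin")]
        se = [GenomicInterval("chr1", 1100, 1200)]
        out = assign_states(annotation, states, super_enhancers=se)
        assert out[("chr1", 1)].state == "SuperEnhancer"

    def test_single_overlap_assigns_that_state(self):
        annotation = self._annotation([_loop(1, 2)])
        states = [StateInterval(GenomicInterval("chr1", 1000, 2000), "Insulator")]
        assert assign_states(annotation, states)[("chr1", 1)].state == "Insulator"

    def test_active_promoter_outranks_weak_enhancer(self):
        annotation = self._annotation([_loop(1, 2)])
        states = [
            StateInterval(GenomicInterval("chr1", 1000, 1500), "WeakEnhancer"),
            StateInterval(GenomicInterval("chr1", 1500, 2000), "ActivePromoter"),
        ]
        assert assign_states(annotation, states)[("chr1", 1)].state == "ActivePromoter"

    def test_total_and_idempotent(self):
        annotation = self._annotation([_loop(1, 2), _loop(3, 7)])
        states = [StateInterval(GenomicInterval("chr1", 3000, 4000), "Insulator")]
        once = assign_states(annotation, states)
        assert all(info.state is not None for info in once.bins.values())
        assert once[("chr1", 7)].state == "Others"  # no overlap -> fallback
        twice = assign_states(once, states)
        assert {b: i.state for b, i in twice.bins.items()} == {
            b: i.state for b, i in once.bins.items()
        }


class TestBreadthAtTSS:
    TSS = [TSSRecord("g", "chr1", 1000, "+")]

    def test_width_of_covering_peak(self):
        peaks = [GenomicInterval("chr1", 900, 4100)]
        assert breadth_at_tss(peaks, self.TSS) == {"g": 3200}

    def test_no_covering_peak_gives_none(self):
        peaks = [GenomicInterval("chr1", 2000, 3000)]
        assert breadth_at_tss(peaks, self.TSS) == {"g": None}

    def test_widest_of_overlapping_peaks_wins(self):
        peaks = [
            GenomicInterval("chr1", 900, 1400),
            GenomicInterval("chr1", 500, 5500),
        ]
        assert breadth_at_tss(peaks, self.TSS) == {"g": 5000}
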