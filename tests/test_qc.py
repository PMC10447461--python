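import numpy as np
import pandas as pd
import pytest
import scipy.sparse

import dropmicro as dm
from dropmicro.errors import InsufficientDataError
from dropmicro.matrix import UmiCountMatrix


def two_gene_matrix(ecoli, bsub, mixed, mixed_counts=(30, 20)):
    """Barcodes with counts on an E. coli gene and/or a B. subtilis gene."""
    rows, names = [], []
    for i in range(ecoli):
        rows.append([50, 0])
        names.append(f"EC{i:04d}")
    for i in range(bsub):
        rows.append([0, 50])
        names.append(f"BS{i:04d}")
    for i in range(mixed):
        rows.append(list(mixed_counts))
        names.append(f"MX{i:04d}")
    return UmiCountMatrix(
        names,
        ["gene_ec", "gene_bs"],
        ["mRNA", "mRNA"],
        scipy.sparse.csr_matrix(np.array(rows)),
    )


SPECIES_MAP = {"gene_ec": "E. coli", "gene_bs": "B. subtilis"}


class TestBarnyard:
    def test_published_mixture_counts_give_1_6_percent(self):
        m = two_gene_matrix(202, 45, 4)
        report = dm.barnyard(m, SPECIES_MAP)
        assert report.mixed_count == 4
        assert report.species_counts == {"E. coli": 202, "B. subtilis": 45}
        assert report.doublet_rate == pytest.approx(4 / 251)
        assert round(report.doublet_rate * 100, 1) == 1.6

    def test_pure_population_has_zero_doublets_full_specificity(self):
        m = two_gene_matrix(50, 1, 0)  # one B. subtilis so >=2 species exist
        report = dm.barnyard(m, SPECIES_MAP)
        assert report.mixed_count == 0
        assert report.specificity["E. coli"] == 1.0

    def test_minor_fraction_and_min_umis_thresholds(self):
        # minor fraction 0.1 < 0.2 -> singlet; minor UMIs 5 < 10 -> singlet
        m = two_gene_matrix(0, 0, 2, mixed_counts=(90, 10))
        assert dm.barnyard(m, SPECIES_MAP).mixed_count == 0
        m = two_gene_matrix(0, 0, 2, mixed_counts=(15, 5))
        assert dm.barnyard(m, SPECIES_MAP).mixed_count == 0
        m = two_gene_matrix(0, 0, 2, mixed_counts=(30, 20))
        assert dm.barnyard(m, SPECIES_MAP).mixed_count == 2

    def test_single_species_annotation_rejected(self):
        m = two_gene_matrix(5, 0, 0)
        with pytest.raises(InsufficientDataError):
            dm.barnyard(m, {"gene_ec": "E. coli", "gene_bs": "E. coli"})

    def test_rate_invariant_to_species_label_order(self):
        m = two_gene_matrix(20, 10, 3)
        a = dm.barnyard(m, SPECIES_MAP)
        swapped = {"gene_ec": "Z species", "gene_bs": "A species"}
        b = dm.barnyard(m, swapped)
        assert a.doublet_rate == b.doublet_rate

    def test_simulated_doublets_labelled_mixed(self):
        profiles = [
            dm.make_species_profile("speciesA", seed=0),
            dm.make_species_profile("speciesB", seed=1),
        ]
        config = dm.SimConfig(
            species=profiles,
            cells_per_species=[150, 150],
            loading_lambda=0.5,
            umi_per_cell_log_mean=np.log(300.0),
            umi_per_cell_log_sigma=0.2,
            seed=14,
        )
        lib = dm.simulate_library(config)
        species_of_gene = {
            g.gene_id: p.name for p in profiles for g in p.genes
        }
        report = dm.barnyard(lib.truth_umi_matrix(), species_of_gene)
        truth = lib.barcode_truth.set_index("barcode")
        true_mixed = set(truth.index[truth["species_set"].str.contains(";")])
        labelled_mixed = set(
            report.per_barcode.loc[report.per_barcode["label"] == "mixed", "barcode"]
        )
        assert labelled_mixed == true_mixed


class TestSaturation:
    def _tagged(self, two_species_library, two_species_demux):
        lib = two_species_library
        assigned = dm.assign_reads(lib.alignments, lib.genes())
        return two_species_demux.tagged.merge(
            assigned[assigned["reason"] == "assigned"], on="read_id"
        )

    def test_depth_zero_and_unattainable(self, two_species_library, two_species_demux):
        tagged = self._tagged(two_species_library, two_species_demux)
        cells = sorted(set(tagged["barcode"]))
        curve = dm.saturation(tagged, cells, depths=(0, 10, 10**7), seed=0)
        assert curve.median_genes[0] == 0.0
        assert not np.isnan(curve.median_genes[1])
        assert np.isnan(curve.median_genes[2])

    def test_full_depth_matches_direct_median(
        self, two_species_library, two_species_demux
    ):
        tagged = self._tagged(two_species_library, two_species_demux)
        cells = sorted(set(tagged["barcode"]))
        depth = len(tagged) // len(cells)
        tagged = tagged.iloc[: depth * len(cells)]  # exact multiple
        curve = dm.saturation(tagged, cells, depths=(depth,), seed=0)
        dedup = tagged.drop_duplicates(["barcode", "gene_id", "umi"])
        direct = (
            dedup.groupby("barcode")["gene_id"]
            .nunique()
            .reindex(cells, fill_value=0)
            .median()
        )
        assert curve.median_genes[0] == pytest.approx(direct)

    def test_monotone_nondecreasing_over_seeds(
        self, two_species_library, two_species_demux
    ):
        tagged = self._tagged(two_species_library, two_species_demux)
        cells = sorted(set(tagged["barcode"]))
        max_depth = len(tagged) // len(cells)
        depths = tuple(
            int(f * max_depth) for f in (0.1, 0.25, 0.5, 0.75, 1.0)
        )
        for seed in (0, 1, 2):
            curve = dm.saturation(tagged, cells, depths=depths, seed=seed)
            vals = [v for v in curve.median_genes if not np.isnan(v)]
            assert all(a <= b + 1e-9 for a, b in zip(vals, vals[1:]))


class TestGeneBodyCoverage:
    def _uniform_alignments(self, gene, n_reads, frag, seed):
        """Fragment starts drawn with overhang so clipped per-base coverage is
        flat in expectation."""
        rng = np.random.default_rng(seed)
        s = rng.integers(gene.start - frag + 1, gene.end + 1, size=n_reads)
        e = s + frag - 1
        s = np.clip(s, gene.start, gene.end)
        e = np.clip(e, gene.start, gene.end)
        return pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(n_reads)],
                "contig": gene.contig,
                "start": s,
                "end": e,
                "strand": "+",
                "unique": 1,
            }
        )

    def test_uniform_coverage_is_flat(self):
        gene = dm.GeneModel("g", "mRNA", "c", 1, 1000, "+")
        aln = self._uniform_alignments(gene, 300_000, 200, seed=0)
        profile = dm.gene_body_coverage(aln, [gene])
        assert profile.shape == (100,)
        assert profile.max() == 1.0
        assert profile.min() > 0.95

    def test_reads_in_first_tenth_only(self):
        gene = dm.GeneModel("g", "mRNA", "c", 1, 1000, "+")
        aln = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(100)],
                "contig": "c",
                "start": 1,
                "end": 100,
                "strand": "+",
                "unique": 1,
            }
        )
        profile = dm.gene_body_coverage(aln, [gene])
        assert (profile[:10] == 1.0).all()
        assert (profile[10:] == 0.0).all()

    def test_reverse_strand_profile_is_mirrored(self):
        fwd = dm.GeneModel("g", "mRNA", "c", 1, 1000, "+")
        rev = dm.GeneModel("g", "mRNA", "c", 1, 1000, "-")
        aln = self._uniform_alignments(fwd, 3000, 80, seed=1)
        # bias coverage toward low genomic coordinates
        aln = aln[aln["start"] < 500]
        pf = dm.gene_body_coverage(aln, [fwd])
        pr = dm.gene_body_coverage(aln, [rev])
        np.testing.assert_allclose(pf, pr[::-1])

    def test_no_qualifying_transcripts_rejected(self):
        gene = dm.GeneModel("g", "mRNA", "c", 1, 50, "+")
        with pytest.raises(InsufficientDataError):
            dm.gene_body_coverage(pd.DataFrame(columns=["contig", "start", "end"]), [gene])

    def test_simulator_decay_gives_decreasing_profile(self):
        profile_sim = dm.make_species_profile("eco", seed=3, n_mrna=30, n_trna=0, n_ncrna=0)
        config = dm.SimConfig(
            species=[profile_sim],
            cells_per_species=[30],
            coverage_decay=0.004,
            umi_per_cell_log_mean=np.log(300.0),
            seed=15,
        )
        lib = dm.simulate_library(config)
        genes = [g for g in lib.genes() if g.length >= 400]
        profile = dm.gene_body_coverage(lib.alignments, genes)
        slope = np.polyfit(np.arange(100), profile, 1)[0]
        assert slope < -0.002
        assert profile[:10].mean() > 2 * profile[-10:].mean()


class TestPseudobulkCorrelation:
    def test_self_correlation_is_one(self, two_species_library):
        m = two_species_library.truth_umi_matrix()
        assert dm.pseudobulk_correlation(m, m) == pytest.approx(1.0)

    def test_replicate_libraries_highly_correlated(self):
        profile = dm.make_species_profile("eco", seed=9)
        libs = []
        for seed in (31, 32):
            config = dm.SimConfig(
                species=[profile],
                cells_per_species=[80],
                umi_per_cell_log_mean=np.log(300.0),
                seed=seed,
            )
            libs.append(dm.simulate_library(config))
        r = dm.pseudobulk_correlation(
            libs[0].truth_umi_matrix(), libs[1].truth_umi_matrix()
        )
        assert r >= 0.95

    def test_too_few_genes_rejected(self):
        m = UmiCountMatrix(
            ["b"], ["g1"], ["mRNA"], scipy.sparse.csr_matrix(np.array([[3]]))
        )
        with pytest.raises(InsufficientDataError):
            dm.pseudobulk_correlation(m, m)
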