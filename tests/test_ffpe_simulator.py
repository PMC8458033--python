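import numpy as np
import pytest
from scipy import stats

from ffpekit.genome_io import GenomeSequence, Window, GenomicInterval, reverse_complement
from ffpekit.ffpe_simulator import (
    SRC_LEN_MAX,
    SRC_LEN_MIN,
    ChimericFragment,
    FragmentRecord,
    ReadProvenance,
    SimConfig,
    SRCPair,
    build_chimeric_fragment,
    generate_acfs,
    inject_sequencing_errors,
    prepare_context,
    read_provenance_tsv,
    sample_spike_weights,
    sample_src_length,
    select_adjacent_pair,
    select_distant_pair,
    simulate_reads,
    write_provenance_tsv,
)

from conftest import ScriptedRng, random_genome


def window_over(genome, chrom="c1", index=0):
    return Window(GenomicInterval(chrom, 0, len(genome.sequences[chrom])), index)


class TestSimConfig:
    def test_derived_adjacent_fraction(self):
        config = SimConfig()
        assert config.adjacent_fraction == pytest.approx(0.43 * 0.63)
        assert config.adjacent_fraction == pytest.approx(0.2709)

    def test_derived_distant_same_chrom_prob(self):
        config = SimConfig()
        expected = (0.43 - 0.2709) / (1 - 0.2709)
        assert config.distant_same_chrom_prob == pytest.approx(expected)
        assert config.distant_same_chrom_prob == pytest.approx(0.218, abs=1e-3)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            SimConfig(acf_prop=1.5)
        with pytest.raises(ValueError):
            SimConfig(coverage=0)
        with pytest.raises(ValueError):
            SimConfig(frag_len_mean=100, read_len=150)


class TestSampleSrcLength:
    def test_degenerate_sigma(self, rng):
        config = SimConfig(src_len_sigma=1e-12)
        draws = {sample_src_length(config, rng) for _ in range(100)}
        assert draws == {6}  # round(e^1.8)

    def test_median_is_six(self, rng):
        config = SimConfig()
        draws = [sample_src_length(config, rng) for _ in range(100_000)]
        assert np.median(draws) == 6

    def test_clamp_low(self, rng):
        config = SimConfig(src_len_mu=np.log(1.2), src_len_sigma=1e-12)
        assert sample_src_length(config, rng) == SRC_LEN_MIN

    def test_clamp_high(self, rng):
        config = SimConfig(src_len_mu=np.log(100.0), src_len_sigma=1e-12)
        assert sample_src_length(config, rng) == SRC_LEN_MAX


class TestSampleSpikeWeights:
    def test_normalized(self, rng):
        weights = sample_spike_weights(4, SimConfig(), rng)
        assert len(weights) == 4
        assert np.all(weights >= 0)
        assert weights.sum() == pytest.approx(1.0)

    def test_beta_mean(self, rng):
        # normalized weights scaled back by n * E[Beta(.5,.5)] recover draws
        n = 100_000
        weights = sample_spike_weights(n, SimConfig(), rng)
        assert weights.sum() * n * 0.5 / n == pytest.approx(0.5, abs=0.01)
        approx_raw = weights * n * 0.5
        assert approx_raw.mean() == pytest.approx(0.5, abs=0.01)

    def test_arcsine_u_shape(self, rng):
        n = 100_000
        weights = sample_spike_weights(n, SimConfig(), rng)
        approx_raw = np.clip(weights * n * 0.5, 0, 1)
        extremes = np.mean((approx_raw < 0.1) | (approx_raw > 0.9))
        middle = np.mean((approx_raw > 0.45) & (approx_raw < 0.55))
        assert extremes > middle

    def test_invalid_n(self, rng):
        with pytest.raises(ValueError):
            sample_spike_weights(0, SimConfig(), rng)


class TestSelectAdjacentPair:
    def test_single_engineered_target(self):
        """A window holding exactly one reverse-complement occurrence at a
        known distance returns that pair (enumeration oracle)."""
        filler = "G" * 500
        seed = "ACCTGA"
        target = reverse_complement(seed)  # TCAGGT
        # seed at 500, target at 610 -> distance 110
        seq = filler + seed + "G" * 104 + target + filler
        genome = GenomeSequence.from_dict({"c1": seq})
        base = np.random.default_rng(0)
        found = 0
        for _ in range(200):
            srng = ScriptedRng(base, [500])  # pin the seed position
            pair = select_adjacent_pair(
                genome, window_over(genome), SimConfig(), srng, src_len=6
            )
            if pair is None:  # different-strand draw finds no occurrence
                continue
            found += 1
            assert pair.same_strand
            assert pair.seed_locus.start == 500
            assert pair.target_locus.start == 610
            assert pair.distance == 110
            pair.validate(genome)
        assert found > 0

    def test_self_match_excluded(self):
        """A palindromic seed whose only revcomp occurrence is itself."""
        seed = "ACGT"  # its own reverse complement
        seq = "G" * 300 + seed + "G" * 300
        genome = GenomeSequence.from_dict({"c1": seq})
        base = np.random.default_rng(1)
        for _ in range(100):
            srng = ScriptedRng(base, [300])
            pair = select_adjacent_pair(
                genome, window_over(genome), SimConfig(), srng, src_len=4
            )
            assert pair is None

    def test_all_a_window_same_strand_none(self):
        genome = GenomeSequence.from_dict({"c1": "A" * 1_000})
        base = np.random.default_rng(2)
        config = SimConfig(same_strand_prop_adjacent=1.0)  # force same strand
        for _ in range(20):
            pair = select_adjacent_pair(
                genome, window_over(genome), config, base, src_len=6
            )
            assert pair is None  # "TTTTTT" absent from an all-A window

    def test_pairs_are_valid_and_within_window(self, mb_genome, rng):
        config = SimConfig()
        from ffpekit.genome_io import partition_windows

        windows = partition_windows(mb_genome, config.window_len)
        returned = 0
        for _ in range(500):
            window = windows[int(rng.integers(0, len(windows)))]
            pair = select_adjacent_pair(mb_genome, window, config, rng)
            if pair is None:
                continue
            returned += 1
            pair.validate(mb_genome)
            assert pair.category == "adjacent"
            assert window.start <= pair.target_locus.start < window.end
            assert pair.distance <= config.window_len
            assert pair.target_locus.start != pair.seed_locus.start
        assert returned > 100

    def test_distance_density_weighting(self):
        """Selection frequencies among planted targets follow the lognormal
        density (chi-square against directly computed weights)."""
        seed = "ACCTGA"
        target = reverse_complement(seed)
        distances = [40, 80, 120, 200, 400, 800]
        seq_list = ["G"] * 3_000
        seed_pos = 100
        seq_list[seed_pos : seed_pos + 6] = list(seed)
        for d in distances:
            seq_list[seed_pos + d : seed_pos + d + 6] = list(target)
        genome = GenomeSequence.from_dict({"c1": "".join(seq_list)})
        config = SimConfig(same_strand_prop_adjacent=1.0)
        base = np.random.default_rng(3)
        picks = []
        for _ in range(5_000):
            srng = ScriptedRng(base, [seed_pos])
            pair = select_adjacent_pair(
                genome, window_over(genome), config, srng, src_len=6
            )
            assert pair is not None
            picks.append(pair.distance)
        density = stats.lognorm.pdf(distances, s=0.35, scale=np.exp(4.7))
        expected = density / density.sum() * len(picks)
        observed = [picks.count(d) for d in distances]
        _, p_value = stats.chisquare(observed, expected)
        assert p_value > 0.001


@pytest.fixture(scope="module")
def two_chrom_ctx():
    genome = random_genome(20, {"c1": 200_000, "c2": 200_000})
    config = SimConfig()
    ctx = prepare_context(genome, config, np.random.default_rng(0))
    return genome, config, ctx


class TestSelectDistantPair:
    def test_target_window_differs_from_seed_window(self, two_chrom_ctx, rng):
        genome, config, ctx = two_chrom_ctx
        seen = 0
        for _ in range(300):
            pair = select_distant_pair(ctx, config, rng)
            if pair is None:
                continue
            seen += 1
            pair.validate(genome)
            seed_w = pair.seed_locus.start // config.window_len
            target_w = pair.target_locus.start // config.window_len
            assert (pair.seed_locus.chrom, seed_w) != (
                pair.target_locus.chrom,
                target_w,
            )
        assert seen > 100

    def test_same_strand_fraction_half(self, two_chrom_ctx):
        genome, config, ctx = two_chrom_ctx
        rng = np.random.default_rng(5)
        flags = []
        while len(flags) < 10_000:
            pair = select_distant_pair(ctx, config, rng)
            if pair is not None:
                flags.append(pair.same_strand)
        assert np.mean(flags) == pytest.approx(0.50, abs=0.02)

    def test_spike_concentration(self, rng):
        """All spike mass on one region confines every seed to it."""
        genome = random_genome(21, {"c1": 40_000})
        config = SimConfig()
        ctx = prepare_context(genome, config, rng)
        hot = 7
        weights = np.zeros(len(ctx.spike_regions))
        weights[hot] = 1.0
        ctx.spike_cum = np.cumsum(weights)
        region = ctx.spike_regions[hot]
        for _ in range(200):
            pair = select_distant_pair(ctx, config, rng)
            if pair is None:
                continue
            assert region.start <= pair.seed_locus.start < region.end

    def test_single_window_genome_errors(self, rng):
        genome = random_genome(22, {"c1": 4_000})
        config = SimConfig()
        ctx = prepare_context(genome, config, rng)
        with pytest.raises(ValueError, match="2 genome windows"):
            select_distant_pair(ctx, config, rng)


class TestBuildChimericFragment:
    def _worked_example_genome(self):
        # A-side context TTTTAC + seed GGAC at [6,10); B-side context AAA +
        # target GTCC (= revcomp(GGAC)) at [17,21).
        seq = "TTTTACGGAC" + "TTTT" + "AAAGTCC" + "GGGG"
        return GenomeSequence.from_dict({"c1": seq})

    def _worked_pair(self):
        return SRCPair(
            seed_locus=GenomicInterval("c1", 6, 10, "+"),
            target_locus=GenomicInterval("c1", 17, 21, "+"),
            src_len=4,
            category="adjacent",
            same_strand=True,
            distance=11,
        )

    def test_worked_example(self):
        genome = self._worked_example_genome()
        srng = ScriptedRng(np.random.default_rng(0), [6])  # a_up = 6
        frag = build_chimeric_fragment(
            genome, self._worked_pair(), 13, SimConfig(read_len=13, frag_len_mean=13.0), srng
        )
        assert frag is not None
        assert frag.sequence == "TTTTACGGACTTT"
        assert frag.junction_offset == 6
        assert frag.src_len == 4
        # read-space intervals [0,10) (A, forward) and [6,13) (B, reverse)
        assert (frag.seg_a.start, frag.seg_a.end, frag.a_dir) == (0, 10, "+")
        assert (frag.seg_b.start, frag.seg_b.end, frag.b_dir) == (14, 21, "-")
        assert reverse_complement(frag.sequence[6:13]) == "AAAGTCC"
        frag.check_structure(genome)

    def test_frag_len_too_small(self):
        genome = self._worked_example_genome()
        with pytest.raises(ValueError, match="too small"):
            build_chimeric_fragment(
                genome, self._worked_pair(), 9, SimConfig(), np.random.default_rng(0)
            )

    def test_src_structure_check_on_generated(self, mb_genome):
        config = SimConfig()
        rng = np.random.default_rng(17)
        ctx = prepare_context(mb_genome, config, rng)
        for frag in generate_acfs(mb_genome, 300, config, rng, ctx):
            frag.check_structure(mb_genome)
            L = frag.src_len
            j = frag.junction_offset
            assert frag.sequence[j : j + L] == frag.src_copy()

    def test_enzymatic_ends_map_to_same_coordinate(self):
        """Same-strand adjacent ACF under enzymatic fragmentation: the two
        fragment ends land on one genomic coordinate."""
        genome = random_genome(30, {"c1": 20_000})
        config = SimConfig(enzymatic_prob=1.0, read_len=50, frag_len_mean=80.0, frag_len_sd=5.0)
        rng = np.random.default_rng(31)
        ctx = prepare_context(genome, config, rng)
        seen = 0
        for _ in range(2_000):
            from ffpekit.genome_io import partition_windows

            windows = partition_windows(genome, config.window_len)
            window = windows[int(rng.integers(0, len(windows)))]
            pair = select_adjacent_pair(genome, window, config, rng)
            if pair is None or not pair.same_strand:
                continue
            frag = build_chimeric_fragment(genome, pair, 80, config, rng)
            if frag is None or not frag.enzymatic:
                continue
            seen += 1
            start_coord = frag.seg_a.start  # fragment start, forward
            end_coord = frag.seg_b.start  # fragment end maps here (reverse)
            assert start_coord == end_coord
        assert seen > 10


class TestGenerateAcfs:
    def test_category_windows(self, mb_genome):
        config = SimConfig()
        rng = np.random.default_rng(23)
        ctx = prepare_context(mb_genome, config, rng)
        acfs = generate_acfs(mb_genome, 200, config, rng, ctx)
        for frag in acfs:
            wa = frag.seg_a.start // config.window_len
            wb = frag.seg_b.start // config.window_len
            if frag.category == "adjacent":
                # SRC loci share a window; segment extents may spill over
                sw = (frag.seg_a.end - frag.src_len) // config.window_len
                tw_lo = frag.seg_b.start // config.window_len
                tw_hi = (frag.seg_b.end - 1) // config.window_len
                assert sw in (tw_lo, tw_hi) or wa == wb
            else:
                assert (frag.seg_a.chrom, wa) != (frag.seg_b.chrom, wb) or abs(wa - wb) >= 1

    def test_src_length_distribution_recovery(self):
        """On an inverted-repeat genome every seed finds a target, so SRC
        lengths must match the rounded/clamped lognormal (two-sample KS
        against a direct-sampling oracle)."""
        rng = np.random.default_rng(40)
        unit = "".join(np.random.default_rng(41).choice(list("ACGT"), size=2_500))
        genome = GenomeSequence.from_dict(
            {"c1": (unit + reverse_complement(unit)) * 4}
        )
        # the genome only offers same-strand (inverted-repeat) targets, so
        # fix the strand too; length availability is then unconditional
        config = SimConfig(
            same_chrom_prop=1.0, adj_given_same_chrom=1.0, same_strand_prop_adjacent=1.0
        )
        ctx = prepare_context(genome, config, rng)
        acfs = generate_acfs(genome, 10_000, config, rng, ctx)
        observed = np.array([f.src_len for f in acfs])
        oracle_rng = np.random.default_rng(99)
        oracle = np.clip(
            np.round(oracle_rng.lognormal(1.8, 0.55, size=10_000)),
            SRC_LEN_MIN,
            SRC_LEN_MAX,
        )
        _, p_value = stats.ks_2samp(observed, oracle)
        assert p_value > 0.001


class TestInjectErrors:
    def test_binomial_rate_q41(self, rng):
        config = SimConfig()
        n = 1_000_000
        seq = "A" * n
        quals = chr(41 + 33) * n
        out = inject_sequencing_errors(seq, quals, config, rng)
        n_sub = sum(1 for a, b in zip(seq, out) if a != b)
        p = 10 ** (-4.1)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(n_sub - n * p) < 3 * sigma

    def test_q0_all_differ(self, rng):
        seq = "ACGTACGT"
        out = inject_sequencing_errors(seq, "!" * 8, SimConfig(), rng)
        assert all(a != b for a, b in zip(seq, out))
        assert set(out) <= set("ACGT")

    def test_empty(self, rng):
        assert inject_sequencing_errors("", "", SimConfig(), rng) == ""

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            inject_sequencing_errors("ACGT", "II", SimConfig(), rng)

    def test_n_untouched(self, rng):
        out = inject_sequencing_errors("N" * 100, "!" * 100, SimConfig(), rng)
        assert out == "N" * 100


class TestReadProvenance:
    @pytest.mark.parametrize(
        "prov",
        [
            ReadProvenance(1, "NORMAL", -1, 0),
            ReadProvenance(123456, "ACF_ADJ", 87, 6),
            ReadProvenance(7, "ACF_DIST", 140, 30),
        ],
    )
    def test_roundtrip(self, prov):
        name = prov.format()
        assert " " not in name and "/" not in name
        assert ReadProvenance.parse(name) == prov

    def test_parse_rejects_foreign_names(self):
        with pytest.raises(ValueError):
            ReadProvenance.parse("read_001")


@pytest.fixture(scope="module")
def sim(tmp_path_factory):
    genome = random_genome(50, {"chr1": 150_000})
    config = SimConfig(coverage=5, acf_prop=0.1, seed=5)
    out = tmp_path_factory.mktemp("sim") / "run"
    result = simulate_reads(genome, None, None, config, np.random.default_rng(5), out)
    return genome, config, result


class TestSimulateReads:
    def test_read_count_arithmetic(self, sim):
        genome, config, result = sim
        n_reads = int(round(config.coverage * genome.total_length / config.read_len))
        n_pairs = n_reads // 2
        assert result.n_reads == 2 * n_pairs
        assert len(result.fragments) == n_pairs
        n_acf = sum(1 for f in result.fragments if f.is_acf)
        assert n_acf == round(config.acf_prop * n_pairs)

    def test_fastq_well_formed(self, sim):
        _, config, result = sim
        lines = result.fastq_r1.read_text().splitlines()
        assert len(lines) == 4 * len(result.fragments)
        assert lines[0].startswith("@SF:")
        assert len(lines[1]) == config.read_len
        assert len(lines[3]) == config.read_len

    def test_r2_is_mate(self, sim):
        genome, config, result = sim
        r1 = result.fastq_r1.read_text().splitlines()
        r2 = result.fastq_r2.read_text().splitlines()
        assert r1[0] == r2[0]  # shared name
        # for a normal fragment without errors the mates come from opposite
        # strands of the same locus; verify via provenance geometry instead
        rec = result.fragments[-1]
        assert rec.kind == "NORMAL"
        assert rec.a_end - rec.a_start == rec.frag_len

    def test_provenance_roundtrip(self, sim, tmp_path):
        _, _, result = sim
        back = read_provenance_tsv(result.provenance_path)
        assert len(back) == len(result.fragments)
        for a, b in zip(back, result.fragments):
            assert a.read_name == b.read_name
            assert (a.chrom_a, a.a_start, a.a_end) == (b.chrom_a, b.a_start, b.a_end)
            assert (a.junction_offset, a.src_len) == (b.junction_offset, b.src_len)

    def test_acf_prop_zero(self, tmp_path):
        genome = random_genome(51, {"chr1": 60_000})
        config = SimConfig(coverage=2, acf_prop=0.0)
        result = simulate_reads(
            genome, None, None, config, np.random.default_rng(1), tmp_path / "z"
        )
        assert all(not f.is_acf for f in result.fragments)
        assert "ACF" not in result.fastq_r1.read_text()

    def test_seeded_byte_reproducibility(self, tmp_path):
        genome = random_genome(52, {"chr1": 60_000})
        config = SimConfig(coverage=3, acf_prop=0.1)
        a = simulate_reads(
            genome, None, None, config, np.random.default_rng(9), tmp_path / "a"
        )
        b = simulate_reads(
            genome, None, None, config, np.random.default_rng(9), tmp_path / "b"
        )
        assert a.fastq_r1.read_bytes() == b.fastq_r1.read_bytes()
        assert a.fastq_r2.read_bytes() == b.fastq_r2.read_bytes()
        assert (
            a.provenance_path.read_text() == b.provenance_path.read_text()
        )

    def test_single_end(self, tmp_path):
        genome = random_genome(53, {"chr1": 60_000})
        config = SimConfig(coverage=2, acf_prop=0.05, paired=False)
        result = simulate_reads(
            genome, None, None, config, np.random.default_rng(2), tmp_path / "se"
        )
        assert result.fastq_r2 is None
        n_reads = int(round(2 * 60_000 / 150))
        assert len(result.fragments) == n_reads

    def test_sv_frequency_mixing(self, tmp_path):
        genome = random_genome(54, {"chr1": 100_000})
        mutated = GenomeSequence.from_dict(
            {"chr1": genome.sequences["chr1"][:50_000]}
        )
        config = SimConfig(coverage=5, acf_prop=0.0, sv_frequency=0.3)
        result = simulate_reads(
            genome, mutated, None, config, np.random.default_rng(3), tmp_path / "mix"
        )
        frac_mut = np.mean([f.haplotype == "mut" for f in result.fragments])
        assert frac_mut == pytest.approx(0.3, abs=0.04)

    def test_wes_mode_targets(self, tmp_path):
        genome = random_genome(55, {"chr1": 200_000})
        bed = tmp_path / "targets.bed"
        bed.write_text("chr1\t50000\t60000\nchr1\t100000\t105000\n")
        config = SimConfig(coverage=20, acf_prop=0.0, target_bed=str(bed))
        result = simulate_reads(
            genome, None, None, config, np.random.default_rng(4), tmp_path / "wes"
        )
        # on-target accounting: reads cover the 15 kb target space
        n_reads = int(round(20 * 15_000 / 150))
        assert result.n_reads == 2 * (n_reads // 2)
        pad = 250
        for rec in result.fragments:
            mid = (rec.a_start + rec.a_end) // 2
            assert (
                50_000 - pad - rec.frag_len <= mid <= 60_000 + pad + rec.frag_len
            ) or (
                100_000 - pad - rec.frag_len <= mid <= 105_000 + pad + rec.frag_len
            )

    def test_profile_mismatch_errors(self, tmp_path):
        from ffpekit.phred_model import uniform_profile

        genome = random_genome(56, {"chr1": 50_000})
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads(
                genome,
                None,
                uniform_profile(100, 30),
                SimConfig(read_len=150),
                np.random.default_rng(0),
                tmp_path / "x",
            )
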