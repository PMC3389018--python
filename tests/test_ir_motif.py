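import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermgenomics.errors import ConfigError, ValidationError
from fermgenomics.ir_motif import (
    MotifModel,
    build_pwm,
    extract_upstream,
    find_inverted_repeats,
    read_fasta,
    reverse_complement,
    scan,
    write_fasta,
)

CORE = "TTGTGCACAA"


def random_promoters(rng, n, length=300):
    return {
        f"p{i}": "".join(rng.choice(list("ACGT"), size=length)) for i in range(n)
    }


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("AAC", "GTT"), (CORE, CORE), ("acgtn", "NACGT")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    @settings(max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGTNacgtn", max_size=40))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq.upper()

    def test_invalid_character_rejected(self):
        with pytest.raises(ValidationError, match="non-DNA"):
            reverse_complement("ACGU")


class TestExtractUpstream:
    GENOME = {"chr": "".join(np.random.default_rng(0).choice(list("ACGT"), 400))}

    def coords(self):
        return pd.DataFrame(
            {
                "gene_id": ["fwd", "rev", "edge"],
                "start": [100, 50, 10],
                "end": [160, 200, 60],
                "strand": ["+", "-", "+"],
            }
        )

    def test_forward_gene(self):
        out = extract_upstream(self.coords(), self.GENOME, length=50)
        assert out["fwd"].seq == self.GENOME["chr"][50:100]
        assert not out["fwd"].truncated

    def test_reverse_gene_is_reverse_complemented(self):
        out = extract_upstream(self.coords(), self.GENOME, length=50)
        assert out["rev"].seq == reverse_complement(self.GENOME["chr"][200:250])

    def test_contig_edge_truncates_and_flags(self):
        out = extract_upstream(self.coords(), self.GENOME, length=50)
        assert out["edge"].seq == self.GENOME["chr"][0:10]
        assert out["edge"].truncated

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            extract_upstream(self.coords(), self.GENOME, length=50, genes=["nope"])


class TestFindInvertedRepeats:
    def plant(self, rng, promoters, genes, site=CORE, strand="+"):
        planted = site if strand == "+" else reverse_complement(site)
        for g in genes:
            seq = promoters[g]
            off = int(rng.integers(0, len(seq) - len(planted)))
            promoters[g] = seq[:off] + planted + seq[off + len(planted) :]

    def test_planted_motif_is_top_ranked(self):
        rng = np.random.default_rng(1)
        fg = random_promoters(rng, 10)
        bg = random_promoters(np.random.default_rng(2), 50)
        self.plant(rng, fg, [f"p{i}" for i in range(8)])
        motifs = find_inverted_repeats(fg, bg)
        assert motifs
        assert CORE in motifs[0].consensus
        assert motifs[0].p_value < 1e-6

    def test_reverse_strand_sites_are_found(self):
        rng = np.random.default_rng(3)
        # an asymmetric-spacer repeat planted only on the reverse strand
        site = "TTGTG" + "AAA" + "CACAA"
        fg = random_promoters(rng, 10)
        bg = random_promoters(np.random.default_rng(4), 40)
        self.plant(rng, fg, [f"p{i}" for i in range(8)], site=site, strand="-")
        motifs = find_inverted_repeats(fg, bg)
        planted_on_forward = reverse_complement(site)
        import re

        def matches_planted(m):
            pattern = m.consensus.replace("N", ".")
            return re.search(pattern, planted_on_forward) is not None

        assert motifs and motifs[0].p_value < 1e-6
        assert any(matches_planted(m) for m in motifs[:3])

    def test_null_foreground_reports_nothing_confident(self):
        confident = 0
        for seed in (10, 11):
            rng = np.random.default_rng(seed)
            fg = random_promoters(rng, 10)
            bg = random_promoters(rng, 50)
            motifs = find_inverted_repeats(fg, bg)
            confident += any(m.q_value < 0.05 for m in motifs)
        assert confident == 0

    def test_invariant_under_global_reverse_complement(self):
        rng = np.random.default_rng(5)
        fg = random_promoters(rng, 8)
        bg = random_promoters(rng, 20)
        self.plant(rng, fg, [f"p{i}" for i in range(6)])
        direct = find_inverted_repeats(fg, bg)
        flipped = find_inverted_repeats(
            {k: reverse_complement(v) for k, v in fg.items()},
            {k: reverse_complement(v) for k, v in bg.items()},
        )
        assert [m.p_value for m in direct] == pytest.approx(
            [m.p_value for m in flipped]
        )

    def test_narrow_arms_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ConfigError, match="degenerate"):
            find_inverted_repeats(
                random_promoters(rng, 3), random_promoters(rng, 3), arm_range=(2, 4)
            )

    def test_empty_sets_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            find_inverted_repeats({}, {"a": "ACGT" * 10})


class TestPwm:
    def test_columns_are_stochastic_and_ic_bounded(self):
        pwm, ic = build_pwm(["TTGTGAAACACAA", "TTGTGTTTCACAA"])
        assert np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9)
        assert (ic >= -1e-9).all() and (ic <= 2.0 + 1e-9).all()

    def test_single_site_zero_pseudocount_limit_is_two_bits(self):
        _, ic = build_pwm(["ACGTACGT"], pseudocount=1e-12)
        assert ic == pytest.approx(2.0, abs=1e-6)


class TestScan:
    def make_motif(self):
        site = "TTGTGAAACACAA"  # arm TTGTG, concrete asymmetric spacer AAA
        pwm, ic = build_pwm([site])
        return (
            MotifModel(
                arm="TTGTG",
                spacer=3,
                pwm=pwm,
                information_content=ic,
                background_freqs=np.full(4, 0.25),
            ),
            site,
        )

    def test_consensus_hits_itself_at_maximal_score(self):
        motif, site = self.make_motif()
        hits = scan(motif, {"s": site})
        assert len(hits) == 1
        assert hits.iloc[0]["offset"] == 0
        assert hits.iloc[0]["strand"] == "+"

    def test_reverse_complement_hits_on_minus_strand(self):
        motif, site = self.make_motif()
        fwd = scan(motif, {"s": site})
        rev = scan(motif, {"s": reverse_complement(site)})
        assert len(rev) == 1
        assert rev.iloc[0]["strand"] == "-"
        assert rev.iloc[0]["score"] == pytest.approx(fwd.iloc[0]["score"])

    def test_all_n_sequence_has_no_hits(self):
        motif, _ = self.make_motif()
        assert scan(motif, {"s": "N" * 40}).empty

    def test_short_sequence_skipped(self):
        motif, _ = self.make_motif()
        assert scan(motif, {"s": "ACGT"}).empty


def test_fasta_round_trip(tmp_path):
    seqs = {"a": "ACGT" * 40, "b": "TTTT"}
    path = tmp_path / "seqs.fasta"
    write_fasta(seqs, path)
    assert read_fasta(path) == seqs
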