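import numpy as np
import pytest

from founderhap.recessive import (
    AnnotatedVariant,
    apply_recessive_model,
    cds_to_codon,
    check_protein_consistency,
    panel_count_filter,
    read_variant_table,
    write_variant_table,
)
from founderhap.simulate import simulate_trio_table
from founderhap.variant_io import Genotype


def make_variant(
    gene="GENE1",
    pos=100,
    proband=Genotype.HOM_ALT,
    mother=Genotype.HET,
    father=Genotype.HET,
    exac=0,
    kg=0,
    cds_pos=None,
    protein_change=None,
    alt="T",
):
    return AnnotatedVariant(
        chrom="chr4", pos=pos, ref="C", alt=alt, gene_id=gene,
        proband_gt=proband, mother_gt=mother, father_gt=father,
        exac_hom_count=exac, kg_hom_count=kg,
        cds_pos=cds_pos, protein_change=protein_change,
    )


class TestRecessiveModel:
    def test_homozygous_candidate_with_het_parents(self):
        cs = apply_recessive_model([make_variant()])
        assert len(cs.homozygous) == 1 and not cs.compound_het_pairs

    def test_compound_het_pairing_one_from_each_parent(self):
        a = make_variant(pos=1, proband=Genotype.HET, mother=Genotype.HET, father=Genotype.HOM_REF)
        b = make_variant(pos=2, proband=Genotype.HET, mother=Genotype.HOM_REF, father=Genotype.HET)
        cs = apply_recessive_model([a, b])
        assert cs.compound_het_pairs == [(a, b)]

    def test_hom_with_hom_ref_parents_excluded(self):
        cs = apply_recessive_model(
            [make_variant(mother=Genotype.HOM_REF, father=Genotype.HOM_REF)]
        )
        assert not cs.homozygous
        assert any("inconsistent" in e.reason for e in cs.log)

    def test_missing_parent_goes_to_unresolved(self):
        cs = apply_recessive_model([make_variant(mother=Genotype.MISSING)])
        assert not cs.homozygous and len(cs.unresolved) == 1

    def test_lenient_mode_accepts_hom_ref_parent(self):
        v = make_variant(mother=Genotype.HOM_REF)
        assert not apply_recessive_model([v]).homozygous
        assert apply_recessive_model([v], lenient_parents=True).homozygous == [v]

    def test_pair_never_shares_transmitting_parent(self):
        # two maternal hets in a gene cannot pair with each other
        a = make_variant(pos=1, proband=Genotype.HET, mother=Genotype.HET, father=Genotype.HOM_REF)
        b = make_variant(pos=2, proband=Genotype.HET, mother=Genotype.HET, father=Genotype.HOM_REF)
        cs = apply_recessive_model([a, b])
        assert not cs.compound_het_pairs

    def test_every_removal_is_logged(self):
        variants = [
            make_variant(pos=1, proband=Genotype.HOM_REF),
            make_variant(pos=2, proband=Genotype.HET, mother=Genotype.HET, father=Genotype.HET),
            make_variant(pos=3, mother=Genotype.HOM_ALT),
        ]
        cs = apply_recessive_model(variants)
        assert not cs.homozygous and not cs.compound_het_pairs
        assert {e.variant_key for e in cs.log} == {v.key for v in variants}


class TestPanelCountFilter:
    def _cs(self, *variants):
        return apply_recessive_model(list(variants))

    @pytest.mark.parametrize(
        "exac,kg,kept",
        [(21, 0, False), (0, 11, False), (20, 10, True), (0, 0, True)],
    )
    def test_exclusive_thresholds(self, exac, kg, kept):
        cs = panel_count_filter(self._cs(make_variant(exac=exac, kg=kg)))
        assert bool(cs.homozygous) is kept
        if not kept:
            assert any(e.stage == "panel_counts" for e in cs.log)

    def test_pair_removed_when_either_member_fails(self):
        a = make_variant(pos=1, proband=Genotype.HET, mother=Genotype.HET,
                         father=Genotype.HOM_REF, exac=0)
        b = make_variant(pos=2, proband=Genotype.HET, mother=Genotype.HOM_REF,
                         father=Genotype.HET, exac=99)
        cs = panel_count_filter(self._cs(a, b))
        assert not cs.compound_het_pairs

    def test_missing_count_treated_as_zero_and_logged(self):
        v = AnnotatedVariant(
            chrom="chr1", pos=5, ref="A", alt="T", gene_id="G",
            proband_gt=Genotype.HOM_ALT, mother_gt=Genotype.HET, father_gt=Genotype.HET,
            exac_hom_count=None, kg_hom_count=None,
        )
        cs = panel_count_filter(self._cs(v))
        assert cs.homozygous == [v]
        assert any("treated as 0" in e.reason for e in cs.log)

    def test_idempotent(self):
        cs1 = panel_count_filter(self._cs(make_variant(exac=3, kg=2)))
        cs2 = panel_count_filter(cs1)
        assert cs2.homozygous == cs1.homozygous
        assert len(cs2.compound_het_pairs) == len(cs1.compound_het_pairs)

    def test_matches_bruteforce_predicate_on_random_tables(self, rng):
        for _ in range(100):
            variants = [
                make_variant(
                    gene=f"G{i}", pos=i + 1,
                    exac=int(rng.integers(0, 40)), kg=int(rng.integers(0, 20)),
                )
                for i in range(30)
            ]
            survivors = panel_count_filter(apply_recessive_model(variants)).homozygous
            expected = [v for v in variants if not (v.exac_hom_count > 20 or v.kg_hom_count > 10)]
            assert survivors == expected


class TestCdsCodon:
    @pytest.mark.parametrize("cds,codon,offset", [(41, 14, 2), (481, 161, 1), (3, 1, 3), (1, 1, 1)])
    def test_codon_and_offset(self, cds, codon, offset):
        assert cds_to_codon(cds) == (codon, offset)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            cds_to_codon(0)

    @pytest.mark.parametrize(
        "cds,p,ok",
        [
            (41, "p.Leu14Pro", True),
            (481, "p.Arg161*", True),
            (41, "p.Leu15Pro", False),
            (41, "completely wrong", False),
            (41, "p.(Leu14Pro)", True),
        ],
    )
    def test_protein_consistency(self, cds, p, ok):
        v = make_variant(cds_pos=cds, protein_change=p)
        passed, message = check_protein_consistency(v)
        assert passed is ok
        assert message  # never silent, never raises on bad HGVS


class TestTableIO:
    def test_round_trip(self, tmp_path):
        variants, _ = simulate_trio_table(n_background=10, seed=5)
        p = tmp_path / "variants.tsv"
        write_variant_table(variants, p)
        back = read_variant_table(p)
        assert back == variants

    def test_missing_columns_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tpos\n1\t2\n")
        with pytest.raises(ValueError, match="ref"):
            read_variant_table(p)


class TestTrioTableSimulator:
    def test_implants_recovered_exactly(self):
        variants, truth = simulate_trio_table(n_background=50, n_homozygous=1,
                                              n_compound_het=1, seed=11)
        cs = panel_count_filter(apply_recessive_model(variants))
        assert [v.key for v in cs.homozygous] == truth["homozygous"]
        assert [(a.key, b.key) for a, b in cs.compound_het_pairs] == truth["compound_het_pairs"]

    def test_no_implant_empty_candidates(self):
        variants, truth = simulate_trio_table(n_background=40, n_homozygous=0,
                                              n_compound_het=0, seed=3)
        cs = panel_count_filter(apply_recessive_model(variants))
        assert not cs.homozygous and not cs.compound_het_pairs
        assert truth == {"homozygous": [], "compound_het_pairs": []}

    def test_deterministic_given_seed(self):
        a, _ = simulate_trio_table(seed=9)
        b, _ = simulate_trio_table(seed=9)
        assert a == b
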