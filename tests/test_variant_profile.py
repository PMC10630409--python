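import random

import pytest

from trialmatch.errors import AnnotationError, ProfileError, VCFParseError
from trialmatch.synthetic_corpus import SPECIFIC_VARIANTS, base_gene_models
from trialmatch.terminology import StandardEntry, Terminology
from trialmatch.variant_profile import (
    Biomarkers,
    GeneModel,
    GeneModelSet,
    PatientProfile,
    Variant,
    annotate_protein_effect,
    biomarker_entries,
    expand_alteration,
    expand_profile,
    load_profile,
    parse_gene_list,
    parse_vcf,
    save_profile,
    write_vcf,
)

EGFR_VCF = """##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=1,Type=String,Description="gene|protein_change">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
7\t55191822\t.\tT\tG\t.\t.\tANN=EGFR|L858R
"""


class TestVCF:
    def test_annotated_record_parsed(self, tmp_path):
        path = tmp_path / "p.vcf"
        path.write_text(EGFR_VCF)
        (v,) = parse_vcf(path)
        assert (v.kind, v.gene_symbol, v.protein_change) == ("snv_indel", "EGFR", "L858R")
        assert (v.contig, v.position, v.ref, v.alt) == ("7", 55191822, "T", "G")

    def test_header_only_vcf_is_empty(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text("\n".join(EGFR_VCF.splitlines()[:3]) + "\n")
        assert parse_vcf(path) == []

    @pytest.mark.parametrize(
        "body,msg",
        [
            ("7\t55191822\t.\tT\tG", "fields"),
            ("7\txx\t.\tT\tG\t.\t.\t.", "POS"),
            ("7\t55191822\t.\t\tG\t.\t.\t.", "REF"),
        ],
    )
    def test_malformed_line_reports_line_number(self, tmp_path, body, msg):
        path = tmp_path / "bad.vcf"
        path.write_text("\n".join(EGFR_VCF.splitlines()[:3] + [body]) + "\n")
        with pytest.raises(VCFParseError, match=msg) as exc:
            parse_vcf(path)
        assert exc.value.line_number == 4

    def test_write_parse_roundtrip(self, tmp_path):
        variants = [v for v in SPECIFIC_VARIANTS.values() if v.kind == "snv_indel"]
        path = tmp_path / "rt.vcf"
        write_vcf(variants, path)
        assert parse_vcf(path) == variants


class TestGeneLists:
    def test_tagged_items(self):
        vs = parse_gene_list("ERBB2:amplification, ALK:fusion\nMET:overexpression")
        assert [(v.gene_symbol, v.kind, v.direction) for v in vs] == [
            ("ERBB2", "cnv", "amplification"),
            ("ALK", "fusion", None),
            ("MET", "expression", "over"),
        ]

    def test_untagged_item_needs_kind(self):
        with pytest.raises(ProfileError):
            parse_gene_list("ERBB2")


class TestAnnotation:
    def test_l858r_lands_in_exon21_with_class(self):
        gm = base_gene_models().get("EGFR")
        av = annotate_protein_effect(Variant("snv_indel", "EGFR", "L858R"), gm)
        assert av.exon_number == 21
        assert av.class_labels == ("Activating mutations",)

    def test_single_exon_toy_gene(self):
        gm = GeneModel("TOY", 10, ((1, 1, 10),))
        av = annotate_protein_effect(Variant("snv_indel", "TOY", "M1V"), gm)
        assert av.exon_number == 1

    def test_position_beyond_protein_raises(self):
        gm = base_gene_models().get("KRAS")
        with pytest.raises(AnnotationError):
            annotate_protein_effect(Variant("snv_indel", "KRAS", "Q999X"), gm)

    def test_missing_model_leaves_unannotated(self):
        av = annotate_protein_effect(Variant("snv_indel", "TP53", "R175H"), None)
        assert av.exon_number is None and av.class_labels == ()

    def test_containment_matches_linear_scan(self):
        rng = random.Random(9)
        for _ in range(40):
            # random non-overlapping intervals
            bounds = sorted(rng.sample(range(1, 400), rng.randint(2, 10) * 2))
            exons = tuple(
                (i + 1, bounds[2 * i], bounds[2 * i + 1])
                for i in range(len(bounds) // 2)
            )
            gm = GeneModel("R", 400, exons)
            for _ in range(10):
                pos = rng.randint(1, 400)
                expected = None
                for n, a, b in exons:
                    if a <= pos <= b:
                        expected = n
                        break
                av = annotate_protein_effect(
                    Variant("snv_indel", "R", f"A{pos}V"), gm
                )
                assert av.exon_number == expected

    def test_model_tsv_roundtrip(self, tmp_path):
        gm = base_gene_models()
        gm.save(tmp_path / "m.tsv", tmp_path / "c.tsv")
        again = GeneModelSet.load(tmp_path / "m.tsv", tmp_path / "c.tsv")
        assert again.models == gm.models


def _ladder_term(names):
    entries = [StandardEntry("G_EGFR", "gene", "EGFR")]
    entries += [StandardEntry(n, "alteration", n) for n in names]
    return Terminology(entries)


class TestExpansion:
    FULL = [
        "EGFR:L858R",
        "EGFR:Activating mutations",
        "EGFR:exon21mut",
        "EGFR:Mutations",
    ]

    def _expand(self, names):
        term = _ladder_term(names)
        gm = base_gene_models().get("EGFR")
        av = annotate_protein_effect(Variant("snv_indel", "EGFR", "L858R"), gm)
        return [term.entries[e].canonical_name for e in expand_alteration(av, term).entries]

    def test_full_ladder_specific_first(self):
        assert self._expand(self.FULL) == self.FULL

    def test_sparse_terminology_filters_ladder(self):
        assert self._expand(["EGFR:Mutations"]) == ["EGFR:Mutations"]

    def test_enlarging_terminology_never_shrinks(self):
        rng = random.Random(2)
        for _ in range(20):
            k = rng.randint(0, len(self.FULL))
            subset = rng.sample(self.FULL, k)
            small = set(self._expand(subset))
            big = set(self._expand(self.FULL))
            assert small <= big

    def test_random_subsets_equal_ordered_intersection(self):
        rng = random.Random(4)
        for _ in range(20):
            subset = [n for n in self.FULL if rng.random() < 0.5]
            assert self._expand(subset) == [n for n in self.FULL if n in subset]

    def test_unresolvable_gene_warns_and_is_empty(self, term):
        av = annotate_protein_effect(Variant("snv_indel", "ZZZ9", "A1V"), None)
        with pytest.warns(UserWarning, match="ZZZ9"):
            assert expand_alteration(av, term).entries == ()

    def test_cnv_ladder(self, term):
        av = annotate_protein_effect(Variant("cnv", "MET", direction="amplification"), None)
        names = [term.entries[e].canonical_name for e in expand_alteration(av, term).entries]
        assert names == ["MET:amplification", "MET:CNV"]


class TestBiomarkers:
    @pytest.mark.parametrize(
        "bm,expected",
        [
            (Biomarkers(tmb=12.0), ["TMB-H"]),
            (Biomarkers(tmb=9.9), []),
            (Biomarkers(tmb="TMB-H"), ["TMB-H"]),
            (Biomarkers(msi="MSI-H", mmr="dMMR"), ["MSI-H", "dMMR"]),
            (Biomarkers(msi="MSS", mmr="pMMR"), []),
        ],
    )
    def test_threshold_and_classes(self, term, bm, expected):
        got = [term.entries[e].canonical_name for e in biomarker_entries(bm, term)]
        assert got == expected


class TestProfiles:
    def test_yaml_roundtrip_random_profiles(self, tmp_path, bundle):
        from trialmatch.synthetic_corpus import generate_patient

        for seed in range(30):
            profile, _ = generate_patient(bundle, seed=seed)
            path = tmp_path / f"p{seed}.yaml"
            save_profile(profile, path)
            again = load_profile(path, terminology=bundle.terminology)
            assert again == profile

    def test_missing_cancer_rejected(self):
        with pytest.raises(ProfileError, match="cancer"):
            load_profile({"variants": []})

    def test_cancer_name_resolves_to_entry(self, term):
        p = load_profile({"cancer": "NSCLC"}, terminology=term)
        assert p.cancer_entry_id == "C_NSCLC"

    def test_vcf_plus_cnv_gene_list(self, tmp_path, term):
        vcf = tmp_path / "v.vcf"
        vcf.write_text("\n".join(EGFR_VCF.splitlines()[:3]) + "\n")
        p = load_profile(
            {
                "cancer": "breast cancer",
                "vcf": str(vcf),
                "gene_lists": ["ERBB2:amplification"],
            },
            terminology=term,
        )
        assert [v.kind for v in p.variants] == ["cnv"]

    def test_expand_profile_collects_all_dimensions(self, term):
        profile = PatientProfile(
            cancer_entry_id="C_NSCLC",
            variants=(Variant("snv_indel", "EGFR", "L858R"),),
            biomarkers=Biomarkers(tmb=15.0),
            prior_therapies=("chemotherapy",),
        )
        xp = expand_profile(profile, term, base_gene_models())
        assert "C_SOLID" in xp.cancer_entries  # ancestor chain
        assert "A_EGFR_L858R" in xp.alteration_entries
        assert "B_TMBH" in xp.biomarker_entry_ids
        assert "T_CHEMO" in xp.prior_entry_ids
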