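"""Seeded synthetic corpora with planted ground truth.

Generates terminologies, gene models, trial records whose eligibility text
is assembled from templates, and patient profiles with known match
outcomes, so every stage of the pipeline (ingest → mine → match) can be
tested end to end without any download.  Templates exercise plain
inclusion and exclusion sentences, exception clauses ("... except X"),
composite alteration+cancer phrases ("HER2-positive breast cancer") and
gene-conjunction sentences ("NSCLC with KEAP1, NFE2L2 and/or STK11
mutation") — deliberately including the two canonical phrasings as fixed
fixtures alongside randomized ones.  By construction every template stays
inside the miner's grammar, so the mined triplets of a generated corpus
equal the planted ground truth exactly.

The same seed always yields byte-identical outputs (single RNG stream).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .criteria_miner import Triplet
from .errors import GenerationError
from .terminology import StandardEntry, Terminology, write_terminology
from .trial_ingest import PHASES, STATUSES, TrialRecord, parse_trial, write_trials
from .variant_profile import (
    Biomarkers,
    GeneModel,
    GeneModelSet,
    PatientProfile,
    Variant,
    expand_profile,
)

# ---------------------------------------------------------------------------
# master entity pools (realistic names; truncated by CorpusSpec pool sizes)
# ---------------------------------------------------------------------------

_E = StandardEntry

_CANCERS = [
    _E("C_SOLID", "cancer", "solid tumor", frozenset({"solid tumour", "advanced solid tumor"})),
    _E("C_LUNG", "cancer", "lung cancer", frozenset(), frozenset({"C_SOLID"})),
    _E("C_NSCLC", "cancer", "non-small cell lung cancer", frozenset({"NSCLC"}), frozenset({"C_LUNG"})),
    _E("C_SCLC", "cancer", "small cell lung cancer", frozenset({"SCLC"}), frozenset({"C_LUNG"})),
    _E("C_BREAST", "cancer", "breast cancer", frozenset(), frozenset({"C_SOLID"})),
    _E("C_CRC", "cancer", "colorectal cancer", frozenset(), frozenset({"C_SOLID"})),
    _E("C_SKIN", "cancer", "skin cancer", frozenset(), frozenset({"C_SOLID"})),
    _E("C_MEL", "cancer", "melanoma", frozenset(), frozenset({"C_SKIN"})),
    _E("C_NMSC", "cancer", "non-melanoma skin cancer", frozenset(), frozenset({"C_SKIN"})),
    _E("C_GASTRIC", "cancer", "gastric cancer", frozenset(), frozenset({"C_SOLID"})),
    _E("C_PANC", "cancer", "pancreatic cancer", frozenset(), frozenset({"C_SOLID"})),
    _E("C_PROSTATE", "cancer", "prostate cancer", frozenset(), frozenset({"C_SOLID"})),
    _E("C_OV", "cancer", "ovarian cancer", frozenset(), frozenset({"C_SOLID"})),
]

_GENE_SYMBOLS = [
    "EGFR", "KRAS", "BRAF", "ALK", "MET", "ERBB2", "KEAP1", "NFE2L2",
    "STK11", "TP53", "PIK3CA", "RET", "ROS1", "BRCA1", "BRCA2", "NTRK1",
]
_GENES = [
    _E(f"G_{g}", "gene", g, frozenset({"HER2"}) if g == "ERBB2" else frozenset())
    for g in _GENE_SYMBOLS
]

# generic alteration-class entries (bare class words found in text)
_GENERIC_ALTERATIONS = [
    _E("A_MUT", "alteration", "mutation", frozenset({"mutations", "mutated"})),
    _E("A_AMP", "alteration", "amplification", frozenset({"amplified"})),
    _E("A_DELETION", "alteration", "deletion", frozenset()),
    _E("A_FUSION", "alteration", "fusion", frozenset({"fusions", "rearrangement"})),
    _E("A_OVX", "alteration", "overexpression", frozenset()),
]

_COMPOSITE_SYNONYMS = {  # gene-level compounds reachable from composite phrases
    "EGFR": frozenset({"EGFR:Mutations", "EGFR-mutant"}),
    "KRAS": frozenset({"KRAS:Mutations", "KRAS-mutant"}),
    "BRAF": frozenset({"BRAF:Mutations", "BRAF-mutant"}),
}


def _gene_level_alterations() -> list[StandardEntry]:
    out = []
    for g in _GENE_SYMBOLS:
        syns = _COMPOSITE_SYNONYMS.get(g, frozenset({f"{g}:Mutations"}))
        out.append(_E(f"A_{g}_MUT", "alteration", f"{g}:mutation", syns))
    return out


_SPECIFIC_ALTERATIONS = [
    _E("A_EGFR_L858R", "alteration", "EGFR:L858R", frozenset({"EGFR L858R"})),
    _E("A_EGFR_T790M", "alteration", "EGFR:T790M", frozenset({"EGFR T790M"})),
    _E("A_EGFR_EX19DEL", "alteration", "EGFR:exon19del", frozenset({"EGFR exon 19 deletion"})),
    _E("A_KRAS_G12C", "alteration", "KRAS:G12C", frozenset({"KRAS G12C"})),
    _E("A_BRAF_V600E", "alteration", "BRAF:V600E", frozenset({"BRAF V600E"})),
    _E("A_EGFR_ACT", "alteration", "EGFR:Activating mutations", frozenset()),
    _E("A_EGFR_EX21", "alteration", "EGFR:exon21mut", frozenset()),
    _E("A_EGFR_EX20", "alteration", "EGFR:exon20mut", frozenset()),
    _E("A_BRAF_ACT", "alteration", "BRAF:Activating mutations", frozenset()),
    _E("A_ERBB2_OVX", "alteration", "ERBB2:overexpression", frozenset({"HER2-positive", "HER2 positive"})),
    _E("A_ERBB2_AMP", "alteration", "ERBB2:amplification", frozenset()),
    _E("A_ERBB2_CNV", "alteration", "ERBB2:CNV", frozenset()),
    _E("A_MET_AMP", "alteration", "MET:amplification", frozenset({"MET amplification"})),
    _E("A_MET_CNV", "alteration", "MET:CNV", frozenset()),
    _E("A_ALK_FUS", "alteration", "ALK:fusion", frozenset({"ALK fusion"})),
    _E("A_RET_FUS", "alteration", "RET:fusion", frozenset({"RET fusion"})),
    _E("A_ROS1_FUS", "alteration", "ROS1:fusion", frozenset({"ROS1 fusion"})),
]

_DRUGS = [
    _E(f"D_{i:02d}", "drug", name)
    for i, name in enumerate(
        [
            "osimertinib", "erlotinib", "trastuzumab", "pembrolizumab", "nivolumab",
            "cisplatin", "carboplatin", "sotorasib", "crizotinib", "docetaxel",
        ]
    )
]

_BIOMARKERS = [
    _E("B_TMB", "biomarker", "TMB", frozenset({"tumor mutational burden"})),
    _E("B_TMBH", "biomarker", "TMB-H", frozenset({"high tumor mutational burden"})),
    _E("B_MSI", "biomarker", "MSI", frozenset({"microsatellite instability"})),
    _E("B_MSIH", "biomarker", "MSI-H", frozenset()),
    _E("B_MMR", "biomarker", "MMR", frozenset({"mismatch repair"})),
    _E("B_DMMR", "biomarker", "dMMR", frozenset()),
    _E("B_PDL1", "biomarker", "PD-L1", frozenset()),
]

_THERAPIES = [
    _E("T_CHEMO", "therapy", "chemotherapy"),
    _E("T_IMMUNO", "therapy", "immunotherapy"),
    _E("T_SURGERY", "therapy", "surgery"),
    _E("T_RADIATION", "therapy", "radiation therapy", frozenset({"radiotherapy"})),
    _E("T_TRANSPLANT", "therapy", "transplantation"),
    _E("T_TARGETED", "therapy", "targeted therapy"),
]

#: variant templates realizing each matchable specific alteration entry
SPECIFIC_VARIANTS: dict[str, Variant] = {
    "A_EGFR_L858R": Variant("snv_indel", "EGFR", "L858R", "7", 55191822, "T", "G"),
    "A_EGFR_T790M": Variant("snv_indel", "EGFR", "T790M", "7", 55181378, "C", "T"),
    "A_KRAS_G12C": Variant("snv_indel", "KRAS", "G12C", "12", 25245351, "C", "A"),
    "A_BRAF_V600E": Variant("snv_indel", "BRAF", "V600E", "7", 140753336, "A", "T"),
    "A_ERBB2_OVX": Variant("expression", "ERBB2", direction="over"),
    "A_ERBB2_AMP": Variant("cnv", "ERBB2", direction="amplification"),
    "A_MET_AMP": Variant("cnv", "MET", direction="amplification"),
    "A_ALK_FUS": Variant("fusion", "ALK"),
    "A_RET_FUS": Variant("fusion", "RET"),
}


def base_terminology() -> Terminology:
    """The full built-in terminology across all six categories."""
    return Terminology(
        _CANCERS
        + _GENES
        + _GENERIC_ALTERATIONS
        + _gene_level_alterations()
        + _SPECIFIC_ALTERATIONS
        + _DRUGS
        + _BIOMARKERS
        + _THERAPIES
    )


def base_gene_models() -> GeneModelSet:
    """Toy protein-coordinate models for the genes that need exon/class data."""
    return GeneModelSet(
        [
            GeneModel(
                "EGFR",
                1210,
                ((18, 688, 728), (19, 729, 761), (20, 762, 823), (21, 824, 875)),
                {"L858R": ("Activating mutations",), "T790M": ()},
            ),
            GeneModel("BRAF", 766, ((15, 581, 620),), {"V600E": ("Activating mutations",)}),
            GeneModel("KRAS", 189, ((2, 1, 37), (3, 38, 97)), {}),
        ]
    )


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a generated corpus; same seed ⇒ identical bytes."""

    seed: int = 0
    n_trials: int = 50
    n_cancers: int = len(_CANCERS)
    n_genes: int = len(_GENE_SYMBOLS)
    n_drugs: int = len(_DRUGS)
    n_therapies: int = len(_THERAPIES)
    n_inclusion_sentences: tuple[int, int] = (1, 4)
    n_exclusion_sentences: tuple[int, int] = (0, 3)
    p_exception: float = 0.25
    p_conjunction: float = 0.35
    p_composite: float = 0.30
    p_negation: float = 0.15
    p_other_passage: float = 0.5
    countries: tuple[str, ...] = ("US", "CN", "DE", "FR", "JP", "GB", "CA", "AU")

    def validate(self) -> None:
        if self.n_trials < 0:
            raise GenerationError("n_trials must be non-negative")
        for name, demand, pool in [
            ("n_cancers", self.n_cancers, len(_CANCERS)),
            ("n_genes", self.n_genes, len(_GENE_SYMBOLS)),
            ("n_drugs", self.n_drugs, len(_DRUGS)),
            ("n_therapies", self.n_therapies, len(_THERAPIES)),
        ]:
            if demand > pool:
                raise GenerationError(f"{name}={demand} exceeds pool size {pool}")
            if name != "n_therapies" and demand < 1 and self.n_trials > 0:
                raise GenerationError(f"{name} must be >= 1 for a non-empty corpus")
        if self.n_genes < 3 and self.p_conjunction > 0 and self.n_trials > 0:
            raise GenerationError("conjunction sentences need a gene pool of >= 3")


@dataclass
class CorpusBundle:
    """A generated corpus plus the bookkeeping that makes it an oracle."""

    spec: CorpusSpec
    terminology: Terminology
    gene_models: GeneModelSet
    trials: list[TrialRecord]
    ground_truth: dict[str, set[tuple[str, str]]]  # trial_id -> {(entry_id, class)}

    def ground_truth_triplets(self, trial_id: str) -> list[Triplet]:
        return sorted(
            (Triplet(eid, cls, trial_id) for eid, cls in self.ground_truth[trial_id]),
            key=lambda t: (t.entry_id, t.criteria_class),
        )

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(self.trials, out / "trials.jsonl")
        write_terminology(self.terminology, out / "terminology.tsv")
        self.gene_models.save(out / "gene_models.tsv", out / "functional_classes.tsv")
        rows = [
            {"trial_id": tid, "entry_id": eid, "criteria_class": cls}
            for tid in sorted(self.ground_truth)
            for eid, cls in sorted(self.ground_truth[tid])
        ]
        pd.DataFrame(rows, columns=["trial_id", "entry_id", "criteria_class"]).to_csv(
            out / "ground_truth.tsv", sep="\t", index=False
        )
        manifest = {"seed": self.spec.seed, "n_trials": self.spec.n_trials}
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def _surface(rng: random.Random, entry: StandardEntry) -> str:
    options = sorted(entry.surfaces)
    return rng.choice(options)


class _TrialBuilder:
    def __init__(self, rng: random.Random, spec: CorpusSpec, term: Terminology):
        self.rng = rng
        self.spec = spec
        self.term = term
        self.cancers = _CANCERS[: spec.n_cancers]
        self.genes = _GENES[: spec.n_genes]
        self.drugs = _DRUGS[: spec.n_drugs]
        self.therapies = _THERAPIES[: spec.n_therapies]
        self.specifics = [
            e for e in _SPECIFIC_ALTERATIONS if e.entry_id in SPECIFIC_VARIANTS
        ]
        self.biomarker_classes = [
            e for e in _BIOMARKERS if e.entry_id in ("B_TMBH", "B_MSIH", "B_DMMR", "B_PDL1")
        ]

    # each sentence builder returns (text, [(entry_id, class-within-block)])

    def _incl_cancer(self):
        c = self.rng.choice(self.cancers)
        return f"Histologically confirmed {_surface(self.rng, c)}.", [(c.entry_id, "inclusion")]

    def _incl_alteration(self):
        a = self.rng.choice(self.specifics)
        return f"Documented {_surface(self.rng, a)}.", [(a.entry_id, "inclusion")]

    def _incl_biomarker(self):
        b = self.rng.choice(self.biomarker_classes)
        return f"Tumors must be {b.canonical_name}.", [(b.entry_id, "inclusion")]

    def _incl_drug(self):
        d = self.rng.choice(self.drugs)
        return f"Eligible for {d.canonical_name} treatment.", [(d.entry_id, "inclusion")]

    def _incl_conjunction(self):
        c = self.rng.choice(self.cancers)
        k = self.rng.choice([2, 3])
        genes = self.rng.sample(self.genes, k)
        names = [g.canonical_name for g in genes]
        listing = ", ".join(names[:-1]) + (" and/or " if k > 1 else "") + names[-1]
        text = f"{_surface(self.rng, c)} with {listing} mutation."
        truth = [(c.entry_id, "inclusion"), ("A_MUT", "inclusion")]
        truth += [(g.entry_id, "inclusion") for g in genes]
        truth += [(f"A_{g.canonical_name}_MUT", "inclusion") for g in genes]
        return text, truth

    def _incl_composite(self):
        comp_id, comp_surface = self.rng.choice(
            [
                ("A_ERBB2_OVX", "HER2-positive"),
                ("A_EGFR_MUT", "EGFR-mutant"),
                ("A_KRAS_MUT", "KRAS-mutant"),
                ("A_BRAF_MUT", "BRAF-mutant"),
            ]
        )
        c = self.rng.choice(self.cancers)
        text = f"{comp_surface} {_surface(self.rng, c)}."
        return text, [(comp_id, "inclusion"), (c.entry_id, "inclusion")]

    def _incl_negation(self):
        t = self.rng.choice(self.therapies)
        return f"No prior {_surface(self.rng, t)}.", [(t.entry_id, "NC")]

    def _excl_therapy(self):
        t = self.rng.choice(self.therapies)
        return f"Prior {_surface(self.rng, t)}.", [(t.entry_id, "exclusion")]

    def _excl_drug(self):
        d = self.rng.choice(self.drugs)
        return f"Previous treatment with {d.canonical_name}.", [(d.entry_id, "exclusion")]

    def _excl_cancer(self):
        c = self.rng.choice(self.cancers)
        return f"Known {_surface(self.rng, c)}.", [(c.entry_id, "exclusion")]

    def _excl_alteration(self):
        a = self.rng.choice(self.specifics)
        return f"{_surface(self.rng, a)} detected.", [(a.entry_id, "exclusion")]

    def _excl_exception(self):
        c = self.rng.choice(self.cancers)
        return (
            f"Any prior malignancy except {_surface(self.rng, c)}.",
            [(c.entry_id, "NC")],
        )

    def build(self, index: int) -> tuple[dict, set[tuple[str, str]]]:
        rng, spec = self.rng, self.spec
        truth: set[tuple[str, str]] = set()
        incl_sentences: list[str] = []
        n_incl = rng.randint(*spec.n_inclusion_sentences)
        builders = [self._incl_cancer, self._incl_alteration, self._incl_biomarker, self._incl_drug]
        for _ in range(max(n_incl, 1)):
            text, t = rng.choice(builders)()
            incl_sentences.append(text)
            truth.update(t)
        if rng.random() < spec.p_conjunction:
            text, t = self._incl_conjunction()
            incl_sentences.append(text)
            truth.update(t)
        if rng.random() < spec.p_composite:
            text, t = self._incl_composite()
            incl_sentences.append(text)
            truth.update(t)
        if rng.random() < spec.p_negation:
            text, t = self._incl_negation()
            incl_sentences.append(text)
            truth.update(t)

        excl_sentences: list[str] = []
        n_excl = rng.randint(*spec.n_exclusion_sentences)
        excl_builders = [self._excl_therapy, self._excl_drug, self._excl_cancer, self._excl_alteration]
        for _ in range(n_excl):
            text, t = rng.choice(excl_builders)()
            excl_sentences.append(text)
            truth.update(t)
        if rng.random() < spec.p_exception:
            text, t = self._excl_exception()
            excl_sentences.append(text)
            truth.update(t)

        eligibility = "Inclusion Criteria:\n" + "\n".join(incl_sentences)
        if excl_sentences:
            eligibility += "\nExclusion Criteria:\n" + "\n".join(excl_sentences)
        passages = [{"type": "eligibility", "text": eligibility}]
        if rng.random() < spec.p_other_passage:
            d = rng.choice(self.drugs)
            c = rng.choice(self.cancers)
            passages.append(
                {
                    "type": "other",
                    "text": f"A study of {d.canonical_name} in {_surface(rng, c)}.",
                }
            )
            truth.update({(d.entry_id, "NA"), (c.entry_id, "NA")})

        metadata = {
            "status": rng.choice(STATUSES),
            "phase": rng.choice(PHASES),
            "gender": rng.choices(["all", "male", "female"], weights=[8, 1, 1])[0],
            "min_age": float(rng.choice([0, 18, 18, 18, 21])),
            "max_age": rng.choice([None, None, 65.0, 75.0, 85.0]),
            "countries": sorted(rng.sample(spec.countries, rng.randint(1, 3))),
        }
        record = {
            "trial_id": f"NCT{index + 1:08d}",
            "title": f"Synthetic precision-oncology trial {index + 1}",
            "metadata": metadata,
            "passages": passages,
        }
        return record, truth


def generate_corpus(spec: CorpusSpec, out_dir: str | Path | None = None) -> CorpusBundle:
    """Generate a corpus; optionally write all files to ``out_dir``."""
    spec.validate()
    rng = random.Random(spec.seed)
    term = base_terminology()
    builder = _TrialBuilder(rng, spec, term)
    trials: list[TrialRecord] = []
    truth: dict[str, set[tuple[str, str]]] = {}
    for i in range(spec.n_trials):
        record, t = builder.build(i)
        trial = parse_trial(record)
        trials.append(trial)
        truth[trial.trial_id] = t
    bundle = CorpusBundle(
        spec=spec,
        terminology=term,
        gene_models=base_gene_models(),
        trials=trials,
        ground_truth=truth,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# patient generation
# ---------------------------------------------------------------------------

_GT_CANDIDACY = ("inclusion", "NA")


def _gt_category(
    bundle: CorpusBundle,
    trial_id: str,
    cancer_chain: frozenset[str],
    variation: frozenset[str],
    mode: str,
) -> str | None:
    """Category implied by the planted ground truth (None = not a candidate).

    Re-applies the matching rules directly on the planted triplet sets, so a
    generated profile's expected outcome never goes through the matcher.
    """
    gt = bundle.ground_truth[trial_id]
    var_cand = any((e, c) in gt for e in variation for c in _GT_CANDIDACY)
    can_cand = any((e, c) in gt for e in cancer_chain for c in _GT_CANDIDACY)
    candidate = {
        "basket": var_cand,
        "umbrella": can_cand,
        "combination": var_cand or can_cand,
    }[mode]
    if not candidate:
        return None
    items = cancer_chain | variation
    if any((e, "exclusion") in gt for e in items):
        return "negative"
    var_incl = any((e, "inclusion") in gt for e in variation)
    can_incl = any((e, "inclusion") in gt for e in cancer_chain)
    positive = {
        "basket": can_incl,
        "umbrella": var_incl,
        "combination": (can_incl and var_cand) or (var_incl and can_cand),
    }[mode]
    return "positive" if positive else "unclassified"


def generate_patient(
    bundle: CorpusBundle,
    seed: int = 0,
    target_outcome: str | None = None,
    mode: str = "basket",
) -> tuple[PatientProfile, dict]:
    """A patient profile, optionally engineered to hit a target category.

    Returns ``(profile, expected)`` where ``expected`` maps ``trial_id`` /
    ``mode`` / ``category`` for the targeted trial (empty for random
    profiles).  Raises :class:`GenerationError` when no combination of a
    built-in variant and cancer realizes the target on any trial.
    """
    rng = random.Random(seed)
    term = bundle.terminology
    cancers = [c.entry_id for c in _CANCERS[: bundle.spec.n_cancers]]
    variant_ids = sorted(SPECIFIC_VARIANTS)

    def chain(c: str) -> frozenset[str]:
        return frozenset({c}) | term.ancestors(c)

    def variation_of(entry_id: str) -> frozenset[str]:
        variant = SPECIFIC_VARIANTS[entry_id]
        expanded = expand_profile(
            PatientProfile(cancer_entry_id=cancers[0], variants=(variant,)),
            term,
            bundle.gene_models,
        )
        return frozenset(expanded.alteration_entries)

    if target_outcome is None:
        cancer = rng.choice(cancers)
        variants = tuple(
            SPECIFIC_VARIANTS[v] for v in rng.sample(variant_ids, rng.randint(1, 2))
        )
        profile = PatientProfile(
            cancer_entry_id=cancer,
            variants=variants,
            biomarkers=Biomarkers(
                tmb=rng.choice([None, 4.0, 12.0]),
                msi=rng.choice(["unknown", "MSS", "MSI-H"]),
                mmr=rng.choice(["unknown", "pMMR", "dMMR"]),
            ),
            age_years=float(rng.randint(25, 80)),
            gender=rng.choice(["male", "female"]),
        )
        return profile, {}

    if target_outcome not in ("positive", "negative", "unclassified"):
        raise GenerationError(f"unknown target outcome {target_outcome!r}")

    trial_ids = sorted(bundle.ground_truth)
    rng.shuffle(trial_ids)
    shuffled_variants = list(variant_ids)
    rng.shuffle(shuffled_variants)
    shuffled_cancers = list(cancers)
    rng.shuffle(shuffled_cancers)
    for tid in trial_ids:
        for v_eid in shuffled_variants:
            variation = variation_of(v_eid)
            for c_eid in shuffled_cancers:
                got = _gt_category(bundle, tid, chain(c_eid), variation, mode)
                if got != target_outcome:
                    continue
                profile = PatientProfile(
                    cancer_entry_id=c_eid,
                    variants=(SPECIFIC_VARIANTS[v_eid],),
                    age_years=40.0,
                    gender="female",
                )
                expected = {"trial_id": tid, "mode": mode, "category": target_outcome}
                return profile, expected
    raise GenerationError(
        f"no profile realizes target {target_outcome!r} in mode {mode!r} on this corpus"
    )
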