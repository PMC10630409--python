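"""Patient profiles and the variant → standard-alteration expansion ladder.

A patient is described by a cancer type (resolved in the cancer
terminology), a variant list (SNV/indel from VCF or pasted tables, plus
CNV / fusion / expression gene lists), biomarker values (TMB, MSI, MMR),
and demographics.  Each variant is expanded into an *ordered* ladder of
standard alteration entries from most specific to most general — e.g. an
EGFR L858R substitution can satisfy ``EGFR:L858R``, ``EGFR:Activating
mutations``, ``EGFR:exon21mut`` and ``EGFR:Mutations`` — so that a trial
standardized on any rung of the ladder is still found.

Protein-level annotation (exon number, functional-class labels) is driven
by a small tabular gene model: exon boundaries as protein-residue
intervals and a ``protein_change → class label`` map.  Pre-annotated
protein changes are accepted directly; the package does not re-implement a
genome annotator, because the mapping ladder — not the annotation — is
what matching needs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from intervaltree import IntervalTree

from .errors import AnnotationError, ProfileError, VCFParseError
from .terminology import Terminology

VARIANT_KINDS = ("snv_indel", "cnv", "fusion", "expression")

#: default TMB-high cutoff in mutations/Mb (configurable everywhere it is used)
TMB_HIGH_THRESHOLD = 10.0


@dataclass(frozen=True)
class Variant:
    kind: str
    gene_symbol: str
    protein_change: str | None = None  # HGVS-p short form, e.g. L858R
    contig: str | None = None
    position: int | None = None  # 1-based
    ref: str | None = None
    alt: str | None = None
    direction: str | None = None  # cnv: amplification/deletion; expression: over/under
    partner_gene: str | None = None  # fusion partner, optional

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ProfileError(f"unknown variant kind {self.kind!r}")
        if self.kind == "snv_indel" and self.protein_change is None and self.position is None:
            raise ProfileError(
                f"snv_indel variant on {self.gene_symbol} needs a protein change "
                "or genomic coordinates"
            )


@dataclass(frozen=True)
class Biomarkers:
    tmb: float | str | None = None  # mut/Mb, or a class string like "TMB-H"
    msi: str = "unknown"  # MSI-H | MSS | unknown
    mmr: str = "unknown"  # dMMR | pMMR | unknown


@dataclass(frozen=True)
class PatientProfile:
    cancer_entry_id: str
    variants: tuple[Variant, ...] = ()
    biomarkers: Biomarkers = Biomarkers()
    age_years: float | None = None
    gender: str | None = None
    countries_of_interest: frozenset[str] = frozenset()
    prior_therapies: tuple[str, ...] = ()  # surfaces resolved at expansion time


# -- gene models ------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Protein-coordinate gene model: numbered exon intervals plus functional classes.

    Exons are ``(exon_number, start_residue, end_residue)`` with 1-based
    closed residue intervals, ordered and non-overlapping; the model may
    cover only part of the protein (residues outside any interval simply
    get no exon-level annotation).
    """

    gene_symbol: str
    protein_length: int
    exons: tuple[tuple[int, int, int], ...]
    functional_classes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        prev_end = 0
        for _n, a, b in self.exons:
            if not (0 < a <= b <= self.protein_length):
                raise AnnotationError(
                    f"{self.gene_symbol}: exon interval {a}-{b} out of bounds"
                )
            if a <= prev_end:
                raise AnnotationError(
                    f"{self.gene_symbol}: exon intervals overlap or are unordered"
                )
            prev_end = b

    def exon_tree(self) -> IntervalTree:
        # half-open tree over closed residue intervals
        return IntervalTree.from_tuples((a, b + 1, n) for n, a, b in self.exons)


class GeneModelSet:
    def __init__(self, models: Iterable[GeneModel]):
        self.models = {m.gene_symbol: m for m in models}

    def get(self, gene_symbol: str) -> GeneModel | None:
        return self.models.get(gene_symbol)

    @classmethod
    def load(
        cls, models_tsv: str | Path, classes_tsv: str | Path | None = None
    ) -> "GeneModelSet":
        """Load models from TSV: ``gene_symbol, protein_length, exons``
        (exons pipe-separated ``number:start-end``), plus an optional class
        table ``gene_symbol, protein_change, class_labels`` (pipe-separated).
        An exon item without the ``number:`` prefix is numbered by position."""
        df = pd.read_csv(models_tsv, sep="\t", dtype=str)
        classes: dict[str, dict[str, tuple[str, ...]]] = {}
        if classes_tsv is not None:
            cdf = pd.read_csv(classes_tsv, sep="\t", dtype=str, keep_default_na=False)
            for r in cdf.itertuples(index=False):
                labels = tuple(x for x in r.class_labels.split("|") if x)
                classes.setdefault(r.gene_symbol, {})[r.protein_change] = labels
        models = []
        for r in df.itertuples(index=False):
            exons = []
            for i, part in enumerate(x for x in r.exons.split("|") if x):
                if ":" in part:
                    num, span = part.split(":", 1)
                else:
                    num, span = str(i + 1), part
                a, b = span.split("-")
                exons.append((int(num), int(a), int(b)))
            models.append(
                GeneModel(
                    gene_symbol=r.gene_symbol,
                    protein_length=int(r.protein_length),
                    exons=tuple(exons),
                    functional_classes=classes.get(r.gene_symbol, {}),
                )
            )
        return cls(models)

    def save(self, models_tsv: str | Path, classes_tsv: str | Path | None = None) -> None:
        rows = [
            {
                "gene_symbol": m.gene_symbol,
                "protein_length": m.protein_length,
                "exons": "|".join(f"{n}:{a}-{b}" for n, a, b in m.exons),
            }
            for m in sorted(self.models.values(), key=lambda m: m.gene_symbol)
        ]
        pd.DataFrame(rows).to_csv(models_tsv, sep="\t", index=False)
        if classes_tsv is not None:
            crows = [
                {
                    "gene_symbol": m.gene_symbol,
                    "protein_change": pc,
                    "class_labels": "|".join(labels),
                }
                for m in sorted(self.models.values(), key=lambda m: m.gene_symbol)
                for pc, labels in sorted(m.functional_classes.items())
            ]
            pd.DataFrame(
                crows, columns=["gene_symbol", "protein_change", "class_labels"]
            ).to_csv(classes_tsv, sep="\t", index=False)


# -- protein-effect annotation ----------------------------------------------

_POSITION_RE = re.compile(r"[A-Za-z*]*?(\d+)")


def protein_position(protein_change: str) -> int | None:
    """First residue number in an HGVS-p short form (L858R → 858)."""
    m = _POSITION_RE.search(protein_change)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Variant
    exon_number: int | None = None
    class_labels: tuple[str, ...] = ()


def annotate_protein_effect(variant: Variant, model: GeneModel | None) -> AnnotatedVariant:
    """Attach exon number and functional-class labels from the gene model.

    With no model for the gene the variant stays unannotated and expansion
    falls back to gene-level terms.  A protein position beyond the protein
    length is an :class:`AnnotationError`.
    """
    if model is None or variant.kind != "snv_indel" or variant.protein_change is None:
        return AnnotatedVariant(variant=variant)
    pos = protein_position(variant.protein_change)
    if pos is None:
        return AnnotatedVariant(variant=variant)
    if pos > model.protein_length:
        raise AnnotationError(
            f"{variant.gene_symbol} residue {pos} beyond protein length "
            f"{model.protein_length}"
        )
    hits = model.exon_tree()[pos]
    exon = min(iv.data for iv in hits) if hits else None
    labels = model.functional_classes.get(variant.protein_change, ())
    return AnnotatedVariant(variant=variant, exon_number=exon, class_labels=labels)


# -- expansion ladder -------------------------------------------------------


@dataclass(frozen=True)
class ExpandedAlteration:
    """Ordered specific-to-general standard entries a variant can satisfy."""

    variant: Variant
    entries: tuple[str, ...]  # entry_ids, most specific first, no duplicates


def _ladder_terms(annotated: AnnotatedVariant) -> list[str]:
    v = annotated.variant
    g = v.gene_symbol
    if v.kind == "snv_indel":
        terms = []
        if v.protein_change:
            terms.append(f"{g}:{v.protein_change}")
        terms.extend(f"{g}:{label}" for label in annotated.class_labels)
        if annotated.exon_number is not None:
            terms.append(f"{g}:exon{annotated.exon_number}mut")
        terms += [f"{g}:Mutations", f"{g}:mutation"]
        return terms
    if v.kind == "cnv":
        direction = v.direction or "amplification"
        return [f"{g}:{direction}", f"{g}:CNV"]
    if v.kind == "fusion":
        terms = []
        if v.partner_gene:
            terms.append(f"{g}-{v.partner_gene}:fusion")
        terms += [f"{g}:fusion", f"{g}:Fusions"]
        return terms
    if v.kind == "expression":
        direction = "overexpression" if (v.direction or "over") == "over" else "underexpression"
        return [f"{g}:{direction}", f"{g}:Expression"]
    raise ProfileError(f"unknown variant kind {v.kind!r}")


def expand_alteration(
    annotated: AnnotatedVariant, terminology: Terminology
) -> ExpandedAlteration:
    """Resolve the ladder against the alteration terminology.

    Only rungs present in the terminology are emitted; order is strictly
    specific-to-general and enlarging the terminology can only add rungs.
    An unresolvable gene yields an empty expansion plus a warning.
    """
    v = annotated.variant
    if not terminology.normalize_mention(v.gene_symbol, "gene"):
        warnings.warn(f"gene symbol {v.gene_symbol!r} does not resolve; empty expansion")
        return ExpandedAlteration(variant=v, entries=())
    entries: list[str] = []
    for term in _ladder_terms(annotated):
        for eid in terminology.normalize_mention(term, "alteration"):
            if eid not in entries:
                entries.append(eid)
    return ExpandedAlteration(variant=v, entries=tuple(entries))


def biomarker_entries(
    biomarkers: Biomarkers,
    terminology: Terminology,
    tmb_threshold: float = TMB_HIGH_THRESHOLD,
) -> list[str]:
    """Standard biomarker entries implied by the measured values.

    TMB at or above the threshold (default 10 mut/Mb) maps to ``TMB-H``;
    MSI-H and dMMR map to their own entries.  Only terms present in the
    biomarker terminology are returned.
    """
    terms = []
    tmb = biomarkers.tmb
    if isinstance(tmb, str):
        terms.append(tmb)
    elif tmb is not None and tmb >= tmb_threshold:
        terms.append("TMB-H")
    if biomarkers.msi == "MSI-H":
        terms.append("MSI-H")
    if biomarkers.mmr == "dMMR":
        terms.append("dMMR")
    out: list[str] = []
    for term in terms:
        for eid in terminology.normalize_mention(term, "biomarker"):
            if eid not in out:
                out.append(eid)
    return out


# -- patient input parsing --------------------------------------------------

_VCF_ANN_RE = re.compile(r"(?:^|;)ANN=([^;]+)")


def parse_vcf(path: str | Path) -> list[Variant]:
    """Read SNV/indel variants from a minimal VCF v4.x file.

    Gene symbol and protein change are taken from an ``ANN=GENE|PCHANGE``
    INFO field when present (the shape a pre-annotated pipeline emits);
    otherwise the variant carries genomic coordinates only, to be resolved
    against a coding-change table.  Malformed body lines raise
    :class:`VCFParseError` with the 1-based line number.
    """
    variants: list[Variant] = []
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VCFParseError(
                    f"expected >=8 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, pos, _id, ref, alt = fields[:5]
            info = fields[7]
            if not pos.isdigit():
                raise VCFParseError(f"non-integer POS {pos!r}", lineno)
            if not ref or not alt or alt == ".":
                raise VCFParseError("missing REF/ALT", lineno)
            gene, pchange = None, None
            m = _VCF_ANN_RE.search(info)
            if m:
                parts = m.group(1).split("|")
                gene = parts[0] or None
                pchange = parts[1] if len(parts) > 1 and parts[1] else None
            variants.append(
                Variant(
                    kind="snv_indel",
                    gene_symbol=gene or "",
                    protein_change=pchange,
                    contig=chrom,
                    position=int(pos),
                    ref=ref,
                    alt=alt,
                )
            )
        if not saw_header and variants:
            raise VCFParseError("missing #CHROM header line", 1)
    return variants


def write_vcf(variants: Sequence[Variant], path: str | Path) -> None:
    """Write SNV/indel variants as a minimal VCF v4.2 (inverse of parse_vcf)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=1,Type=String,Description="gene|protein_change">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        if v.kind != "snv_indel":
            continue
        ann = f"ANN={v.gene_symbol}|{v.protein_change or ''}"
        lines.append(
            "\t".join(
                [
                    v.contig or "1",
                    str(v.position or 1),
                    ".",
                    v.ref or "N",
                    v.alt or "N",
                    ".",
                    ".",
                    ann,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


_GENE_LIST_KIND = {
    "amplification": ("cnv", "amplification"),
    "deletion": ("cnv", "deletion"),
    "fusion": ("fusion", None),
    "overexpression": ("expression", "over"),
    "underexpression": ("expression", "under"),
    "over": ("expression", "over"),
    "under": ("expression", "under"),
}


def parse_gene_list(text: str, kind: str | None = None) -> list[Variant]:
    """Parse newline/comma-separated gene symbols with kind tags.

    Each item is ``GENE`` (requires ``kind``) or ``GENE:tag`` where the tag
    selects the variant kind, e.g. ``ERBB2:amplification``, ``ALK:fusion``,
    ``MET:overexpression``.
    """
    variants = []
    for item in re.split(r"[\n,]+", text):
        item = item.strip()
        if not item:
            continue
        if ":" in item:
            gene, tag = item.split(":", 1)
            tag = tag.strip().casefold()
            if tag not in _GENE_LIST_KIND:
                raise ProfileError(f"unknown gene-list tag {tag!r} in {item!r}")
            vkind, direction = _GENE_LIST_KIND[tag]
        elif kind is not None:
            gene, vkind, direction = item, kind, None
        else:
            raise ProfileError(f"gene-list item {item!r} lacks a kind tag")
        variants.append(Variant(kind=vkind, gene_symbol=gene.strip(), direction=direction))
    return variants


def load_profile(
    source: str | Path | dict, terminology: Terminology | None = None
) -> PatientProfile:
    """Load a patient profile from YAML (path or already-parsed mapping).

    Recognized keys: ``cancer`` (name or entry id — required), ``variants``
    (list of variant mappings), ``vcf`` (path, merged in), ``gene_lists``
    (text blocks in :func:`parse_gene_list` syntax), ``biomarkers``
    (``tmb``/``msi``/``mmr``), ``age``, ``gender``, ``countries``,
    ``prior_therapies``.
    """
    base = Path(".")
    if not isinstance(source, dict):
        base = Path(source).parent
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = source
    cancer = data.get("cancer")
    if not cancer:
        raise ProfileError("profile is missing the cancer type")
    cancer_entry_id = str(cancer)
    if terminology is not None:
        if cancer_entry_id not in terminology:
            hits = terminology.normalize_mention(cancer_entry_id, "cancer")
            if not hits:
                raise ProfileError(f"cancer {cancer!r} does not resolve")
            cancer_entry_id = hits[0]
    variants: list[Variant] = []
    for v in data.get("variants", []):
        variants.append(
            Variant(
                kind=v.get("kind", "snv_indel"),
                gene_symbol=v["gene"],
                protein_change=v.get("protein_change"),
                contig=v.get("contig"),
                position=v.get("position"),
                ref=v.get("ref"),
                alt=v.get("alt"),
                direction=v.get("direction"),
                partner_gene=v.get("partner"),
            )
        )
    if data.get("vcf"):
        vcf_path = Path(data["vcf"])
        if not vcf_path.is_absolute():
            vcf_path = base / vcf_path
        variants.extend(parse_vcf(vcf_path))
    for block in data.get("gene_lists", []):
        variants.extend(parse_gene_list(str(block)))
    bm = data.get("biomarkers", {}) or {}
    return PatientProfile(
        cancer_entry_id=cancer_entry_id,
        variants=tuple(variants),
        biomarkers=Biomarkers(
            tmb=bm.get("tmb"), msi=bm.get("msi", "unknown"), mmr=bm.get("mmr", "unknown")
        ),
        age_years=data.get("age"),
        gender=data.get("gender"),
        countries_of_interest=frozenset(data.get("countries", [])),
        prior_therapies=tuple(data.get("prior_therapies", [])),
    )


def profile_to_dict(profile: PatientProfile) -> dict:
    """Serialize a profile to the YAML mapping accepted by load_profile."""
    out: dict = {"cancer": profile.cancer_entry_id}
    if profile.variants:
        out["variants"] = []
        for v in profile.variants:
            d = {"kind": v.kind, "gene": v.gene_symbol}
            for key, val in [
                ("protein_change", v.protein_change),
                ("contig", v.contig),
                ("position", v.position),
                ("ref", v.ref),
                ("alt", v.alt),
                ("direction", v.direction),
                ("partner", v.partner_gene),
            ]:
                if val is not None:
                    d[key] = val
            out["variants"].append(d)
    bm = profile.biomarkers
    if bm.tmb is not None or bm.msi != "unknown" or bm.mmr != "unknown":
        out["biomarkers"] = {}
        if bm.tmb is not None:
            out["biomarkers"]["tmb"] = bm.tmb
        if bm.msi != "unknown":
            out["biomarkers"]["msi"] = bm.msi
        if bm.mmr != "unknown":
            out["biomarkers"]["mmr"] = bm.mmr
    if profile.age_years is not None:
        out["age"] = profile.age_years
    if profile.gender is not None:
        out["gender"] = profile.gender
    if profile.countries_of_interest:
        out["countries"] = sorted(profile.countries_of_interest)
    if profile.prior_therapies:
        out["prior_therapies"] = list(profile.prior_therapies)
    return out


def save_profile(profile: PatientProfile, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(profile_to_dict(profile), sort_keys=True))


# -- whole-profile expansion ------------------------------------------------


@dataclass(frozen=True)
class ExpandedProfile:
    """A profile with every matchable dimension resolved to entry ids."""

    profile: PatientProfile
    cancer_entries: frozenset[str]  # profile cancer plus its ancestors
    alteration_entries: frozenset[str]
    biomarker_entry_ids: frozenset[str]
    prior_entry_ids: frozenset[str]
    expansions: tuple[ExpandedAlteration, ...]

    @property
    def variation_entries(self) -> frozenset[str]:
        """The variation dimension used by matching: alterations + biomarkers."""
        return self.alteration_entries | self.biomarker_entry_ids

    @property
    def all_entries(self) -> frozenset[str]:
        return self.variation_entries | self.cancer_entries | self.prior_entry_ids


def expand_profile(
    profile: PatientProfile,
    terminology: Terminology,
    gene_models: GeneModelSet | None = None,
    tmb_threshold: float = TMB_HIGH_THRESHOLD,
) -> ExpandedProfile:
    """Expand every variant and biomarker of a profile into standard entries."""
    if profile.cancer_entry_id not in terminology:
        raise ProfileError(f"cancer entry {profile.cancer_entry_id!r} not in terminology")
    expansions = []
    for v in profile.variants:
        model = gene_models.get(v.gene_symbol) if gene_models is not None else None
        annotated = annotate_protein_effect(v, model)
        expansions.append(expand_alteration(annotated, terminology))
    alteration_entries = frozenset(e for x in expansions for e in x.entries)
    prior: set[str] = set()
    for surface in profile.prior_therapies:
        for eid in terminology.normalize_mention(surface):
            if terminology.entries[eid].category in ("therapy", "drug"):
                prior.add(eid)
    return ExpandedProfile(
        profile=profile,
        cancer_entries=frozenset({profile.cancer_entry_id})
        | terminology.ancestors(profile.cancer_entry_id),
        alteration_entries=alteration_entries,
        biomarker_entry_ids=frozenset(
            biomarker_entries(profile.biomarkers, terminology, tmb_threshold)
        ),
        prior_entry_ids=frozenset(prior),
        expansions=tuple(expansions),
    )
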