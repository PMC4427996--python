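"""Relaxed symplesiomorphy / synapomorphy character-site detection.

At slowly evolving alignment positions, a character site records a single
substitution along one bipartition of a rooted tree. For a focal ingroup
(one form of one paralog family), with the other form of the same family as
sister group and the opposing family as outgroup:

* a **symplesiomorphy** (shared ancestral state) is a residue class shared
  by >50% of the ingroup and >50% of the outgroup while absent from every
  sister-group taxon — the sister group changed, the ingroup retained the
  ancestral state;
* a **synapomorphy** (shared derived state) is a residue class held by
  >50% of the ingroup and absent from every sister-group and outgroup
  taxon — the ingroup changed.

The definition is deliberately relaxed: the shared residue need not be
perfectly conserved within a group, because derived lineages may have
accumulated further substitutions. Physiochemically similar residues may
be pooled into one class (e.g. R/K) when at least two class members are
present, letting conservative within-class drift count toward the share.
All share comparisons are strict (> threshold) on raw fractions of non-gap
residues; percentages are rounded half-up for display only.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from paralogsites.io import AMINO_ACIDS, Alignment, TaxonGrouping

#: residue classes pooled by default: conservative substitutions that
#: preserve charge (K/R, D/E), aliphatic bulk (L/M/I/V), aromaticity
#: (F/Y/W) or hydroxyl character (S/T).
DEFAULT_SIMILARITY_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("KR"),
    frozenset("DE"),
    frozenset("LMIV"),
    frozenset("FYW"),
    frozenset("ST"),
)

#: coarse physiochemical super-categories used to grade a substitution as
#: conservative (within category) or radical (across categories); proline
#: stands alone for its backbone geometry.
DEFAULT_SUPER_CATEGORIES: Mapping[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIMFWC"),
    "polar": frozenset("STNQYG"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "proline": frozenset("P"),
}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SimilarityScheme:
    """Named, pairwise-disjoint residue classes; unlisted residues are
    implicit singletons. Also carries the super-categories for radicality
    grading."""

    classes: tuple[frozenset[str], ...] = DEFAULT_SIMILARITY_CLASSES
    super_categories: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_SUPER_CATEGORIES)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cls in self.classes:
            overlap = seen & cls
            if overlap:
                raise ValueError(f"residue {sorted(overlap)} in more than one class")
            bad = cls - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"non-amino-acid residues in class: {sorted(bad)}")
            seen |= cls

    def class_of(self, residue: str) -> frozenset[str]:
        """Full scheme class containing `residue` (singleton if unlisted)."""
        if residue not in AMINO_ACIDS:
            raise KeyError(f"unknown residue {residue!r}")
        for cls in self.classes:
            if residue in cls:
                return cls
        return frozenset((residue,))

    def super_category(self, residue: str) -> str:
        for name, members in self.super_categories.items():
            if residue in members:
                return name
        raise KeyError(f"residue {residue!r} not in any super-category")

    @classmethod
    def from_dict(cls, spec: Mapping) -> "SimilarityScheme":
        """Build from a YAML/JSON-style mapping with optional keys
        ``classes`` (list of residue strings) and ``super_categories``
        (name -> residue string)."""
        classes = tuple(
            frozenset(c) for c in spec.get("classes", ("KR", "DE", "LMIV", "FYW", "ST"))
        )
        cats = {
            k: frozenset(v)
            for k, v in spec.get(
                "super_categories", {k: "".join(sorted(v)) for k, v in DEFAULT_SUPER_CATEGORIES.items()}
            ).items()
        }
        return cls(classes, cats)


@dataclass(frozen=True)
class CharSiteParams:
    """Detector tuning.

    share_threshold
        Strict lower bound on the within-group share of the defining class
        (default 0.5, i.e. ">50%").
    absence_scope
        ``residue``: the specific shared residues must be absent from every
        sister taxon; ``class``: the whole scheme class must be absent.
    outgroup_pooling
        ``pooled``: outgroup share computed over all outgroup taxa combined
        (taxon-weighted); ``per-form-majority``: the class must exceed the
        threshold within every outgroup form separately.
    min_nongap_fraction
        A group with a smaller non-gap fraction at a column is ineligible
        and the column is not called.
    """

    share_threshold: float = 0.5
    absence_scope: str = "residue"
    outgroup_pooling: str = "pooled"
    min_nongap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.share_threshold < 1.0:
            raise ValueError("share_threshold must be in (0, 1)")
        if not 0.0 < self.min_nongap_fraction <= 1.0:
            raise ValueError("min_nongap_fraction must be in (0, 1]")
        if self.absence_scope not in ("residue", "class"):
            raise ValueError(f"unknown absence_scope {self.absence_scope!r}")
        if self.outgroup_pooling not in ("pooled", "per-form-majority"):
            raise ValueError(f"unknown outgroup_pooling {self.outgroup_pooling!r}")


@dataclass(frozen=True)
class GroupProfile:
    """Residue-class composition of one group at one column.

    Counts are over non-gap, non-X residues. ``dominant_class`` is the
    candidate class (singleton residue, or pooled scheme class when at
    least two members are present) with the largest count; its share is a
    raw fraction of the non-gap count, its percent rounded half-up.
    """

    label: str
    n_taxa: int
    n_nongap: int
    residue_counts: Mapping[str, int]
    dominant_class: tuple[str, ...] | None
    dominant_share: float
    eligible: bool

    @property
    def dominant_percent(self) -> int | None:
        if self.dominant_class is None:
            return None
        return _round_half_up(100.0 * self.dominant_share)

    def display(self, threshold: float = 0.5) -> str:
        """Table-style cell: ``R/K(80)`` above threshold, else
        ``not conserved`` (or ``.`` for an ineligible group)."""
        if not self.eligible or self.dominant_class is None:
            return "."
        if self.dominant_share > threshold:
            return f"{'/'.join(self.dominant_class)}({self.dominant_percent})"
        return "not conserved"


@dataclass(frozen=True)
class CharSiteCall:
    """Classification of one column for one ingroup."""

    column: int
    classification: str  # symplesiomorphy | synapomorphy | none
    ingroup: tuple[str, str]  # (family, form)
    defining_class: tuple[str, ...] | None
    ingroup_share: float | None
    outgroup_share: float | None
    profiles: Mapping[str, GroupProfile]
    radical: str | None = None  # radical | conservative
    weak: bool = False
    reason: str | None = None

    @property
    def ingroup_label(self) -> str:
        return f"{self.ingroup[0]}:{self.ingroup[1]}"

    @property
    def is_call(self) -> bool:
        return self.classification != "none"

    @property
    def counts_for_headline(self) -> bool:
        return self.is_call and not self.weak


def _candidate_classes(
    counts: Counter, scheme: SimilarityScheme
) -> list[tuple[tuple[str, ...], int]]:
    """Candidate (class, count) pairs: singleton residues first, then
    opportunistically pooled scheme classes whose >=2 members are present;
    each list sorted by descending count (ties: alphabetical)."""
    singles = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out: list[tuple[tuple[str, ...], int]] = [((r,), n) for r, n in singles]
    for cls in scheme.classes:
        present = [r for r, _ in singles if r in cls]
        if len(present) >= 2:
            out.append((tuple(present), sum(counts[r] for r in present)))
    out.sort(key=lambda cn: (-cn[1], len(cn[0]), cn[0]))
    # move singletons ahead of pooled classes with equal count: a single
    # residue is the more specific defining class
    return out


def group_residue_profile(
    alignment: Alignment,
    column: int,
    taxa: Sequence[str],
    scheme: SimilarityScheme | None = None,
    *,
    label: str = "group",
    min_nongap_fraction: float = 0.5,
) -> GroupProfile:
    """Residue-class profile of `taxa` at 1-based `column`."""
    if not taxa:
        raise ValueError("empty taxa set")
    scheme = scheme or SimilarityScheme()
    col = alignment.column(column)
    index = {t: i for i, t in enumerate(alignment.taxon_ids)}
    residues = [col[index[t]] for t in taxa]
    counts = Counter(r for r in residues if r not in ("-", "X"))
    return _profile_from_counts(label, len(taxa), counts, scheme, min_nongap_fraction)


def _profile_from_counts(
    label: str,
    n_taxa: int,
    counts: Counter,
    scheme: SimilarityScheme,
    min_nongap_fraction: float,
) -> GroupProfile:
    n_nongap = sum(counts.values())
    eligible = n_nongap >= min_nongap_fraction * n_taxa and n_nongap > 0
    if not counts:
        return GroupProfile(label, n_taxa, 0, {}, None, 0.0, False)
    candidates = _candidate_classes(counts, scheme)
    best_cls, best_n = candidates[0]
    return GroupProfile(
        label,
        n_taxa,
        n_nongap,
        dict(counts),
        best_cls,
        best_n / n_nongap,
        eligible,
    )


def radicality(
    class_a: Iterable[str], class_b: Iterable[str], scheme: SimilarityScheme | None = None
) -> str:
    """Grade the difference between two residue classes.

    ``conservative`` iff all residues of both classes fall in one and the
    same physiochemical super-category; otherwise ``radical``.
    """
    scheme = scheme or SimilarityScheme()
    cats = {scheme.super_category(r) for r in class_a}
    cats |= {scheme.super_category(r) for r in class_b}
    return "conservative" if len(cats) == 1 else "radical"


def _share(counts: Counter, cls: tuple[str, ...]) -> float:
    n = sum(counts.values())
    if n == 0:
        return 0.0
    return sum(counts[r] for r in cls) / n


def _absent(counts: Counter, cls: tuple[str, ...], scope: str, scheme: SimilarityScheme) -> bool:
    if scope == "class":
        watched: set[str] = set()
        for r in cls:
            watched |= scheme.class_of(r)
    else:
        watched = set(cls)
    return all(counts[r] == 0 for r in watched)


def _evaluate_from_counts(
    column: int,
    ingroup: tuple[str, str],
    in_counts: Counter,
    in_n: int,
    sis_counts: Counter,
    sis_n: int,
    out_counts: Counter,
    out_n: int,
    out_form_counts: Mapping[str, tuple[Counter, int]],
    profiles: Mapping[str, GroupProfile],
    scheme: SimilarityScheme,
    params: CharSiteParams,
) -> CharSiteCall:
    thr = params.share_threshold
    none_call = CharSiteCall(
        column, "none", ingroup, None, None, None, profiles
    )

    def eligible(counts: Counter, n: int) -> bool:
        ng = sum(counts.values())
        return n > 0 and ng > 0 and ng >= params.min_nongap_fraction * n

    if not (
        eligible(in_counts, in_n)
        and eligible(sis_counts, sis_n)
        and eligible(out_counts, out_n)
    ):
        return replace(none_call, reason="coverage")

    def outgroup_supports(cls: tuple[str, ...]) -> bool:
        if params.outgroup_pooling == "pooled":
            return _share(out_counts, cls) > thr
        return all(
            _share(c, cls) > thr for c, n in out_form_counts.values() if n > 0
        )

    sister_dom = profiles.get("sister")
    sister_dom_class = sister_dom.dominant_class if sister_dom else None

    def grade(cls: tuple[str, ...]) -> str | None:
        if sister_dom_class is None:
            return None
        return radicality(cls, sister_dom_class, scheme)

    candidates = _candidate_classes(in_counts, scheme)
    weak_candidate: CharSiteCall | None = None
    for cls, n in candidates:
        in_share = n / sum(in_counts.values())
        if in_share <= thr:
            break  # sorted descending: nothing below can pass
        if not _absent(sis_counts, cls, params.absence_scope, scheme):
            continue
        out_share = _share(out_counts, cls)
        if outgroup_supports(cls):
            return CharSiteCall(
                column,
                "symplesiomorphy",
                ingroup,
                cls,
                in_share,
                out_share,
                profiles,
                radical=grade(cls),
            )
        if _absent(out_counts, cls, params.absence_scope, scheme):
            return CharSiteCall(
                column,
                "synapomorphy",
                ingroup,
                cls,
                in_share,
                out_share,
                profiles,
                radical=grade(cls),
            )
        # shared with only a plurality of the outgroup: a weak
        # symplesiomorphy, reported but kept out of headline counts
        out_candidates = _candidate_classes(out_counts, scheme)
        if weak_candidate is None and out_candidates and set(out_candidates[0][0]) & set(cls):
            weak_candidate = CharSiteCall(
                column,
                "symplesiomorphy",
                ingroup,
                cls,
                in_share,
                out_share,
                profiles,
                radical=grade(cls),
                weak=True,
            )
    if weak_candidate is not None:
        return weak_candidate
    return none_call


def _group_layout(
    grouping: TaxonGrouping, ingroup: tuple[str, str]
) -> tuple[tuple[str, ...], tuple[str, ...], dict[str, tuple[str, ...]]]:
    """Resolve (ingroup taxa, sister taxa, outgroup form -> taxa)."""
    family, form = ingroup
    in_taxa = grouping.group(family, form)
    if not in_taxa:
        raise ValueError(f"ingroup {family}:{form} has no taxa")
    sis_taxa = tuple(
        t
        for t, (fam, fo) in grouping.assignments.items()
        if fam == family and fo != form
    )
    out_forms: dict[str, tuple[str, ...]] = {}
    for fam in grouping.families():
        if fam == family:
            continue
        for fo in grouping.forms(fam):
            out_forms[f"{fam}:{fo}"] = grouping.group(fam, fo)
    if not sis_taxa:
        raise ValueError(f"ingroup {family}:{form} has no sister form")
    if not out_forms:
        raise ValueError(f"ingroup {family}:{form} has no outgroup family")
    return in_taxa, sis_taxa, out_forms


def evaluate_site(
    alignment: Alignment,
    column: int,
    grouping: TaxonGrouping,
    scheme: SimilarityScheme | None = None,
    params: CharSiteParams | None = None,
    ingroup: tuple[str, str] = ("A", "rare"),
) -> CharSiteCall:
    """Classify one column for one ingroup.

    The sister group is the other form of the ingroup's family; the
    outgroup is every taxon of the other family (pooled or per-form per
    ``params.outgroup_pooling``).
    """
    scheme = scheme or SimilarityScheme()
    params = params or CharSiteParams()
    in_taxa, sis_taxa, out_forms = _group_layout(grouping, ingroup)

    col = alignment.column(column)
    index = {t: i for i, t in enumerate(alignment.taxon_ids)}

    def counts_of(taxa: Sequence[str]) -> Counter:
        return Counter(
            col[index[t]] for t in taxa if col[index[t]] not in ("-", "X")
        )

    in_counts = counts_of(in_taxa)
    sis_counts = counts_of(sis_taxa)
    out_form_counts = {
        label: (counts_of(taxa), len(taxa)) for label, taxa in out_forms.items()
    }
    out_counts: Counter = Counter()
    for c, _ in out_form_counts.values():
        out_counts.update(c)
    out_n = sum(len(t) for t in out_forms.values())

    mnf = params.min_nongap_fraction
    profiles = {
        "ingroup": _profile_from_counts(
            f"{ingroup[0]}:{ingroup[1]}", len(in_taxa), in_counts, scheme, mnf
        ),
        "sister": _profile_from_counts("sister", len(sis_taxa), sis_counts, scheme, mnf),
    }
    for label, (c, n) in out_form_counts.items():
        profiles[label] = _profile_from_counts(label, n, c, scheme, mnf)

    return _evaluate_from_counts(
        column,
        ingroup,
        in_counts,
        len(in_taxa),
        sis_counts,
        len(sis_taxa),
        out_counts,
        out_n,
        out_form_counts,
        profiles,
        scheme,
        params,
    )


def scan_charsites(
    alignment: Alignment,
    grouping: TaxonGrouping,
    scheme: SimilarityScheme | None = None,
    params: CharSiteParams | None = None,
    ingroups: Sequence[tuple[str, str]] | None = None,
    *,
    columns: Sequence[int] | None = None,
    include_none: bool = False,
) -> list[CharSiteCall]:
    """Classify every column for every requested ingroup.

    Returns calls with classification != none (unless ``include_none``),
    sorted by column then ingroup. Default ingroups are all (family, form)
    groups in the grouping.
    """
    scheme = scheme or SimilarityScheme()
    params = params or CharSiteParams()
    grouping.validate_against(alignment)
    if ingroups is None:
        ingroups = [
            (fam, fo) for fam in grouping.families() for fo in grouping.forms(fam)
        ]
    if columns is None:
        columns = range(1, alignment.n_columns + 1)

    arr = alignment.to_array()
    index = {t: i for i, t in enumerate(alignment.taxon_ids)}
    layouts = {ig: _group_layout(grouping, ig) for ig in ingroups}
    row_idx = {
        ig: (
            [index[t] for t in in_t],
            [index[t] for t in sis_t],
            {lbl: [index[t] for t in taxa] for lbl, taxa in outf.items()},
        )
        for ig, (in_t, sis_t, outf) in layouts.items()
    }

    calls: list[CharSiteCall] = []
    mnf = params.min_nongap_fraction
    for col in columns:
        column_chars = arr[:, col - 1]
        for ig in ingroups:
            in_idx, sis_idx, out_idx = row_idx[ig]

            def counts_of(idx: list[int]) -> Counter:
                return Counter(
                    str(c) for c in (column_chars[i] for i in idx) if c not in ("-", "X")
                )

            in_counts = counts_of(in_idx)
            sis_counts = counts_of(sis_idx)
            out_form_counts = {
                lbl: (counts_of(idx), len(idx)) for lbl, idx in out_idx.items()
            }
            out_counts: Counter = Counter()
            for c, _ in out_form_counts.values():
                out_counts.update(c)
            out_n = sum(len(idx) for idx in out_idx.values())

            profiles = {
                "ingroup": _profile_from_counts(
                    f"{ig[0]}:{ig[1]}", len(in_idx), in_counts, scheme, mnf
                ),
                "sister": _profile_from_counts(
                    "sister", len(sis_idx), sis_counts, scheme, mnf
                ),
            }
            for lbl, (c, n) in out_form_counts.items():
                profiles[lbl] = _profile_from_counts(lbl, n, c, scheme, mnf)

            call = _evaluate_from_counts(
                col,
                ig,
                in_counts,
                len(in_idx),
                sis_counts,
                len(sis_idx),
                out_counts,
                out_n,
                out_form_counts,
                profiles,
                scheme,
                params,
            )
            if call.is_call or include_none:
                calls.append(call)
    calls.sort(key=lambda c: (c.column, c.ingroup))
    return calls


@dataclass(frozen=True)
class CharSiteReport:
    """Aggregate of a scan: headline counts and per-family conservation."""

    symplesiomorphy_counts: Mapping[tuple[str, str], int]
    synapomorphy_counts: Mapping[tuple[str, str], int]
    weak_counts: Mapping[tuple[str, str], int]
    mean_conservation: Mapping[str, float | None]  # family -> rounded mean %
    calls: tuple[CharSiteCall, ...]

    def to_dict(self) -> dict:
        def keyed(m: Mapping[tuple[str, str], int]) -> dict[str, int]:
            return {f"{fam}:{fo}": n for (fam, fo), n in m.items()}

        return {
            "symplesiomorphies": keyed(self.symplesiomorphy_counts),
            "synapomorphies": keyed(self.synapomorphy_counts),
            "weak_symplesiomorphies": keyed(self.weak_counts),
            "mean_conservation_percent": dict(self.mean_conservation),
        }


def summarize_calls(calls: Sequence[CharSiteCall]) -> CharSiteReport:
    """Headline counts per ingroup and mean within-ingroup conservation.

    Weak calls are tallied separately and excluded from headline counts.
    Mean conservation per family is the rounded mean, over that family's
    (non-weak) symplesiomorphy sites across both of its forms, of the
    defining class's share within the calling ingroup — expressed in
    percent; ``None`` when the family has no such sites.
    """
    sympl: Counter = Counter()
    synap: Counter = Counter()
    weak: Counter = Counter()
    per_family_shares: dict[str, list[float]] = {}
    for call in calls:
        if not call.is_call:
            continue
        if call.weak:
            weak[call.ingroup] += 1
            continue
        if call.classification == "symplesiomorphy":
            sympl[call.ingroup] += 1
            per_family_shares.setdefault(call.ingroup[0], []).append(
                100.0 * call.ingroup_share
            )
        elif call.classification == "synapomorphy":
            synap[call.ingroup] += 1
    mean_cons = {
        fam: float(_round_half_up(sum(v) / len(v))) if v else None
        for fam, v in per_family_shares.items()
    }
    return CharSiteReport(
        dict(sympl), dict(synap), dict(weak), mean_cons, tuple(calls)
    )


def write_charsite_report(
    calls: Sequence[CharSiteCall],
    path,
    *,
    threshold: float = 0.5,
) -> None:
    """Table-layout TSV: one row per call, a profile column per group."""
    group_labels: list[str] = []
    for call in calls:
        for lbl in call.profiles:
            if lbl not in ("ingroup", "sister") and lbl not in group_labels:
                group_labels.append(lbl)
    with open(path, "w") as fh:
        header = [
            "site",
            "ingroup",
            "classification",
            "defining_class",
            "ingroup_profile",
            "sister_profile",
            *group_labels,
            "radicality",
            "weak",
        ]
        fh.write("\t".join(header) + "\n")
        for call in calls:
            row = [
                str(call.column),
                call.ingroup_label,
                call.classification,
                "/".join(call.defining_class) if call.defining_class else "NA",
                call.profiles["ingroup"].display(threshold),
                call.profiles["sister"].display(threshold),
                *(
                    call.profiles[lbl].display(threshold) if lbl in call.profiles else "."
                    for lbl in group_labels
                ),
                call.radical or "NA",
                str(call.weak).lower(),
            ]
            fh.write("\t".join(row) + "\n")
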