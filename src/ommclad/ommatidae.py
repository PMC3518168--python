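"""The Ommatidae study matrix: 28 taxa x 28 unordered characters.

The matrix covers two outgroup taxa (the permocupedid *Permocupes
sojanensis* and the cupedid *Platycupes dolichocerus*) and 26 ingroup
ommatids spanning both extant genera (*Omma*, *Tetraphalerus*) and
thirteen extinct genera.  Character 4 (gular sutures) is the single
three-state character; all characters are unordered and equally
weighted.  ``?`` marks states unobservable in the material (mostly
compression fossils), ``-`` states rendered inapplicable by the absence
or fusion of the bearing structure (e.g. the labrum/clypeus ratio in
*Omma*, where the labrum is fused with the clypeus, or window-puncture
size in taxa whose elytral disk lacks window punctures).

Every cell is generated from an explicit per-character coding rule so
that it can be audited: each character carries the list of taxa (or
whole genera) assigned to each state, a default for the unlisted
remainder (a concrete state where the source statement enumerates one
side of an exhaustive contrast, otherwise ``?``), and species-level
overrides.  :func:`provenance_table` exports these rules as rows.
"""

from __future__ import annotations

import numpy as np

from .matrix import (CharacterDefinition, CharacterMatrix, TaxonSet,
                     MISSING, INAPPLICABLE)

__all__ = ["TAXA", "OUTGROUP", "ommatidae_matrix", "ommatidae_outgroup",
           "constraint_group", "provenance_table"]

TAXA: tuple[str, ...] = (
    "Permocupes_sojanensis",
    "Platycupes_dolichocerus",
    "Omma_delicata",
    "Omma_stanleyi",
    "Omma_mastersii",
    "Omma_gobiense",
    "Pareuryomma_tylodes",
    "Pareuryomma_ancistrodonta",
    "Pareuryomma_cardiobasis",
    "Cionocoleus_cervicalis",
    "Odontomma_trachylaena",
    "Brochocoleus_applanatus",
    "Liassocupes_parvus",
    "Tetraphalerus_decorosus",
    "Tetraphalerus_bruchi",
    "Tetraphalerus_wagneri",
    "Tetraphalerus_brevicapits",
    "Tetraphalerus_glabratus",
    "Notocupoides_triassicus",
    "Rhabdocupes_longus",
    "Zygadenia_viridis",
    "Notocupes_pingi",
    "Notocupes_nigrimonticola",
    "Eurydictyon_conspicuum",
    "Amblomma_psilata",
    "Amblomma_porrecta",
    "Lithocupes_punctatus",
    "Tetraphalerites_oligocenicus",
)

OUTGROUP: tuple[str, ...] = TAXA[:2]

_GENERA: dict[str, list[str]] = {}
for _t in TAXA:
    _GENERA.setdefault(_t.split("_")[0], []).append(_t)

#: Genus membership used for constraint groups.  The sensitivity option
#: of adding the morphogenus Zygadenia to Notocupes is exposed through
#: :func:`constraint_group`.
GENUS_GROUPS = {g: tuple(m) for g, m in _GENERA.items()}

# ---------------------------------------------------------------------
# Per-character coding.  Tuple fields:
#   label, n_states, default, {state: [taxa or genera]}, {taxon: state},
#   source note (quoted from the character-state discussion, condensed).
# A genus name expands to all its sampled species.
_CODING = [
    ("dorsal head keel", 2, "1",
     {"0": ["Notocupoides", "Notocupes", "Rhabdocupes", "Zygadenia",
            "Eurydictyon", "Amblomma", "Permocupes", "Platycupes"]},
     {},
     "keel present in the six notocupedine-grade genera and both outgroups; "
     "absent elsewhere"),
    ("posteromesal dorsal protuberance", 2, "?",
     {"0": ["Platycupes", "Tetraphalerus", "Notocupoides", "Eurydictyon",
            "Notocupes", "Rhabdocupes", "Zygadenia", "Lithocupes",
            "Liassocupes", "Amblomma"],
      "1": ["Omma_stanleyi", "Omma_mastersii", "Cionocoleus", "Pareuryomma",
            "Odontomma", "Brochocoleus"]},
     {"Omma_delicata": "1"},
     "protuberance present/absent lists; extant Omma scored absent, "
     "O. delicata absent per its description (no dorsal prominences)"),
    ("median epicranial suture", 2, "?",
     {"1": ["Omma", "Cionocoleus"],
      "0": ["Notocupoides", "Notocupes", "Rhabdocupes", "Zygadenia",
            "Eurydictyon", "Amblomma", "Tetraphalerus", "Pareuryomma",
            "Brochocoleus", "Permocupes", "Platycupes"]},
     {},
     "suture absent in Omma and Cionocoleus, distinct in the listed genera"),
    ("ventrolateral antennal grooves", 2, "0",
     {"1": ["Tetraphalerus"]},
     {"Tetraphalerus_decorosus": "?"},
     "grooves an autapomorphy of Tetraphalerus; not visible in the "
     "T. decorosus fossil"),
    ("gular sutures", 3, "?",
     {"0": ["Platycupes", "Permocupes", "Eurydictyon", "Notocupoides",
            "Notocupes", "Rhabdocupes", "Zygadenia", "Amblomma"],
      "1": ["Omma_stanleyi", "Omma_mastersii"],
      "2": ["Tetraphalerus_bruchi", "Tetraphalerus_wagneri"]},
     {"Pareuryomma_ancistrodonta": "0", "Pareuryomma_cardiobasis": "0"},
     "complete / incomplete / absent; the two new Pareuryomma species show "
     "sutures reaching the hind margin"),
    ("gular sutures converging posteriorly", 2, "?",
     {"0": ["Platycupes", "Notocupoides", "Rhabdocupes", "Notocupes",
            "Zygadenia", "Amblomma", "Permocupes"],
      "1": ["Omma_stanleyi", "Omma_mastersii"]},
     {"Tetraphalerus_bruchi": "-", "Tetraphalerus_wagneri": "-",
      "Pareuryomma_ancistrodonta": "0", "Pareuryomma_cardiobasis": "0"},
     "diverging / converging; inapplicable where the sutures are absent; "
     "new Pareuryomma species have a subrectangular gula narrowing "
     "anteriorly"),
    ("frontoclypeal suture", 2, "?",
     {"0": ["Notocupoides", "Rhabdocupes", "Notocupes", "Eurydictyon",
            "Amblomma", "Permocupes"],
      "1": ["Omma_stanleyi", "Omma_mastersii", "Tetraphalerus_bruchi",
            "Tetraphalerus_wagneri"]},
     {},
     "present in the listed fossil genera; usually absent in extant "
     "Archostemata, so the four extant species are scored absent"),
    ("labrum/clypeus width ratio", 2, "?",
     {"1": ["Amblomma", "Brochocoleus", "Pareuryomma", "Odontomma",
            "Cionocoleus", "Lithocupes"],
      "0": ["Tetraphalerus", "Permocupes"],
      "-": ["Omma"]},
     {},
     "labrum narrower than clypeus vs as wide; labrum fused with clypeus "
     "in Omma, hence inapplicable"),
    ("anterior margin of labrum", 2, "?",
     {"0": ["Notocupoides", "Rhabdocupes", "Notocupes", "Eurydictyon",
            "Amblomma", "Lithocupes", "Cionocoleus", "Odontomma",
            "Omma_stanleyi", "Omma_mastersii", "Permocupes", "Platycupes"],
      "1": ["Pareuryomma", "Brochocoleus", "Tetraphalerus"]},
     {},
     "convex vs truncate; Omma is listed under the convex state, applied "
     "to the extant species only"),
    ("antennal length", 2, "1",
     {"0": ["Platycupes"]},
     {"Permocupes_sojanensis": "?"},
     "antennae strongly elongated in Cupedidae, moderately long or short "
     "in Ommatidae"),
    ("pedicel length", 2, "1",
     {"0": ["Notocupoides", "Eurydictyon", "Pareuryomma", "Permocupes"]},
     {},
     "pedicel not shortened in the four listed taxa, greatly shortened in "
     "the other taxa under consideration"),
    ("length of third antennomere", 2, "1",
     {"0": ["Permocupes", "Platycupes", "Notocupoides", "Rhabdocupes",
            "Notocupes", "Zygadenia", "Eurydictyon", "Pareuryomma"]},
     {},
     "about as long as the fourth in the listed taxa, distinctly elongated "
     "in the other ommatid tribes"),
    ("apical flagellomere", 2, "1",
     {"0": ["Pareuryomma", "Tetraphalerus_decorosus", "Permocupes"]},
     {},
     "apically rounded and inflated in Pareuryomma, T. decorosus and "
     "Permocupedidae; parallel-sided elsewhere"),
    ("mandible length", 2, "0",
     {"1": ["Tetraphalerus", "Cionocoleus", "Omma_gobiense"]},
     {},
     "exceptionally long and protruding in Tetraphalerus, Cionocoleus and "
     "Omma gobiense; species-level coding follows the text for Omma"),
    ("mandibular cutting edge", 2, "0",
     {"1": ["Omma_stanleyi", "Omma_mastersii", "Tetraphalerus_bruchi",
            "Tetraphalerus_wagneri", "Pareuryomma_tylodes",
            "Pareuryomma_cardiobasis"]},
     {"Pareuryomma_ancistrodonta": "0", "Omma_delicata": "?",
      "Tetraphalerus_decorosus": "?"},
     "vertically arranged teeth characteristic of extant Ommatidae and "
     "toothed Pareuryomma; horizontal in Cupedidae and most fossils; "
     "P. ancistrodonta has a single apical tooth; teeth not recognisable "
     "in O. delicata and T. decorosus"),
    ("pronotum shape", 2, "0",
     {"1": ["Pareuryomma"]},
     {},
     "narrowing posteriorly only in Pareuryomma"),
    ("pronotal surface convexities", 2, "0",
     {"1": ["Omma", "Cionocoleus", "Odontomma"]},
     {},
     "only absent in Omma, Cionocoleus and Odontomma"),
    ("lateral pronotal projection", 2, "1",
     {"0": ["Notocupoides", "Rhabdocupes", "Notocupes", "Zygadenia",
            "Eurydictyon", "Amblomma", "Cionocoleus", "Pareuryomma",
            "Brochocoleus", "Odontomma", "Lithocupes", "Platycupes"]},
     {},
     "paranota widened in the twelve listed genera"),
    ("procoxae", 2, "1",
     {"0": ["Permocupes", "Platycupes"]},
     {},
     "adjacent in Ommatidae, distinctly divided in Cupedidae and "
     "Permocupes"),
    ("last/penultimate ventrite length ratio", 2, "0",
     {"1": ["Liassocupes", "Notocupoides", "Rhabdocupes", "Zygadenia",
            "Eurydictyon", "Lithocupes", "Amblomma", "Platycupes",
            "Tetraphalerus_wagneri"]},
     {},
     "last ventrite longer in the listed taxa; T. wagneri's is as long as "
     "the two preceding ventrites together"),
    ("arrangement of abdominal sterna", 2, "?",
     {"1": ["Platycupes", "Notocupoides", "Rhabdocupes", "Notocupes",
            "Zygadenia", "Eurydictyon", "Amblomma"],
      "0": ["Brochocoleus", "Odontomma", "Pareuryomma", "Omma",
            "Cionocoleus", "Tetraphalerus"]},
     {},
     "overlapping in Cupedidae and the listed genera, abutting in the "
     "others"),
    ("length of mesofemur", 2, "?",
     {"0": ["Omma", "Cionocoleus", "Brochocoleus", "Odontomma",
            "Notocupoides", "Rhabdocupes", "Notocupes", "Zygadenia",
            "Eurydictyon", "Lithocupes"],
      "1": ["Tetraphalerus", "Amblomma", "Pareuryomma"]},
     {},
     "extending well beyond the body margin vs short"),
    ("main elytral veins", 2, "0",
     {"1": ["Rhabdocupes", "Notocupes", "Zygadenia", "Eurydictyon",
            "Amblomma", "Brochocoleus"]},
     {},
     "two longitudinal main veins meeting before the elytral apex in the "
     "listed genera"),
    ("epipleural rim near base", 2, "0",
     {"1": ["Pareuryomma", "Odontomma", "Brochocoleus"]},
     {},
     "more than one row of cells basally in the three listed genera"),
    ("window punctures on elytral disk", 2, "0",
     {"1": ["Cionocoleus", "Tetraphalerites", "Omma_delicata",
            "Omma_gobiense", "Tetraphalerus_decorosus",
            "Tetraphalerus_brevicapits", "Tetraphalerus_glabratus"]},
     {},
     "absent or very indistinct in Cionocoleus, Tetraphalerites and the "
     "extinct species of Omma and Tetraphalerus"),
    ("size of window punctures", 2, "1",
     {"0": ["Eurydictyon", "Notocupes", "Notocupoides", "Amblomma",
            "Platycupes"],
      "-": ["Cionocoleus", "Tetraphalerites", "Omma_delicata",
            "Omma_gobiense", "Tetraphalerus_decorosus",
            "Tetraphalerus_brevicapits", "Tetraphalerus_glabratus"]},
     {},
     "enlarged, rib-separated punctures in the listed taxa and "
     "Triadocupedinae; inapplicable where disk punctures are absent"),
    ("marginal row of large window punctures", 2, "1",
     {"0": ["Eurydictyon", "Notocupes", "Notocupoides", "Amblomma",
            "Lithocupes", "Liassocupes", "Pareuryomma", "Odontomma",
            "Brochocoleus", "Platycupes"]},
     {},
     "regular marginal row present in the listed genera and "
     "Triadocupedinae"),
    ("pentagonal sutural window punctures", 2, "0",
     {"1": ["Eurydictyon", "Notocupoides"]},
     {},
     "present only in Eurydictyon and Notocupoides"),
]


def _expand(names: list[str]) -> list[str]:
    out: list[str] = []
    for name in names:
        if name in _GENERA:
            out.extend(_GENERA[name])
        else:
            if name not in TAXA:
                raise KeyError(f"unknown taxon or genus {name!r}")
            out.append(name)
    return out


_SYMBOL = {"?": MISSING, "-": INAPPLICABLE}


def ommatidae_matrix() -> CharacterMatrix:
    """Build the packaged 28 x 28 Ommatidae matrix."""
    n, c = len(TAXA), len(_CODING)
    cells = np.empty((n, c), dtype=np.int8)
    chars = []
    tindex = {t: i for i, t in enumerate(TAXA)}
    for j, (label, n_states, default, groups, overrides, _src) in enumerate(_CODING):
        col = {t: default for t in TAXA}
        for state, names in groups.items():
            for t in _expand(names):
                col[t] = state
        col.update(overrides)
        for t, s in col.items():
            cells[tindex[t], j] = _SYMBOL[s] if s in _SYMBOL else int(s)
        chars.append(CharacterDefinition(j, label, n_states))
    return CharacterMatrix(list(TAXA), chars, cells)


def ommatidae_outgroup() -> TaxonSet:
    return TaxonSet("outgroup", frozenset(OUTGROUP))


def constraint_group(*genera: str, name: str | None = None,
                     include_zygadenia: bool = False) -> TaxonSet:
    """A constraint group built from genus membership.

    ``constraint_group("Tetraphalerus", "Odontomma")`` gives the taxon
    set whose enforced monophyly is tested in the constrained analyses.
    ``include_zygadenia`` optionally adds the morphogenus *Zygadenia*
    to a group containing *Notocupes* (sensitivity option; default off).
    """
    members: set[str] = set()
    for g in genera:
        if g not in GENUS_GROUPS:
            raise KeyError(f"unknown genus {g!r}")
        members.update(GENUS_GROUPS[g])
    if include_zygadenia and "Notocupes" in genera:
        members.update(GENUS_GROUPS["Zygadenia"])
    return TaxonSet(name or "+".join(genera), frozenset(members))


def provenance_table() -> list[dict[str, str]]:
    """Audit rows: one per (character, state-group or override)."""
    rows = []
    for j, (label, n_states, default, groups, overrides, src) in enumerate(_CODING):
        rows.append({"character": str(j), "label": label, "kind": "default",
                     "state": default, "taxa": "<unlisted>", "source": src})
        for state, names in groups.items():
            rows.append({"character": str(j), "label": label, "kind": "group",
                         "state": state, "taxa": ",".join(_expand(names)),
                         "source": src})
        for t, state in overrides.items():
            rows.append({"character": str(j), "label": label,
                         "kind": "override", "state": state, "taxa": t,
                         "source": src})
    return rows
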