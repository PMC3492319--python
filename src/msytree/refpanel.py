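"""Packaged reference panel: the basal-MSY survey encoded as fixtures.

This module materializes, entirely in code, the worked dataset the
package documents itself against: a Karafet-style backbone of the deepest
portion of the human Y-chromosome tree (redrawn on the revised root, with
the A1b lineage as one of the two basal branches), a catalog combining

* the 22 newly described mutations (parsed from the packaged table, with
  their printed GRCh37 coordinates, including the multi-copy V249 and the
  3-bp deletions V303/V304),
* previously reported mutations, and
* the backbone-defining markers,

and a genotype matrix for 51 representative chromosomes typed per-panel
(A1b, A1a, A2, A3, B, CT, C, F), with one ancestral control from the
sibling clade per panel encoding the polarity knowledge carried over from
the discovery sequencing.

Naming honesty: marker names not printed anywhere (branch-by-branch lists
of the previously reported mutations, and the B2c-defining backbone
marker) are clearly synthetic placeholders with prefix ``Z``; see
``MANIFEST``.  The fixture is synthetic in that sense — it is the
published statements re-expressed as data, not a deposited dataset.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

from .genotypes import ANCESTRAL, DERIVED, NO_CALL, GenotypeMatrix, SampleRecord
from .markers import (
    DELETION,
    MULTI_COPY,
    SUBSTITUTION,
    Marker,
    MarkerCatalog,
    OutgroupAllele,
    parse_marker_table,
    write_marker_table,
    write_outgroup_table,
)
from .tree import HaplogroupNode, HaplogroupTree, write_newick

__all__ = ["ReferencePanel", "reference_panel", "new_mutation_table", "write_fixture",
           "AFRICAN_CLADES"]

AFRICAN_CLADES = ("A", "B")


def _s(lo: int, hi: int) -> list[str]:
    return [f"s{i:02d}" for i in range(lo, hi + 1)]


def _z(lo: int, hi: int) -> list[str]:
    return [f"Z{i:03d}" for i in range(lo, hi + 1)]


@dataclass
class PanelSpec:
    """One per-haplogroup genotyping panel: who was typed at what."""

    samples: list[str]
    markers: list[str]
    controls: list[str]


@dataclass
class ReferencePanel:
    backbone: HaplogroupTree
    catalog: MarkerCatalog
    matrix: GenotypeMatrix
    outgroup: dict[str, OutgroupAllele]
    panels: dict[str, PanelSpec]
    manifest: str


def new_mutation_table() -> MarkerCatalog:
    """The 22 newly described mutations, parsed from the packaged table."""
    ref = importlib.resources.files("msytree.data").joinpath("new_mutations.tsv")
    with ref.open("r") as fh:
        return parse_marker_table(fh)


# ---------------------------------------------------------------------------
# backbone


def _leaf(name: str, markers: list[str], lineage: str | None = None,
          collapsed: int = 0) -> HaplogroupNode:
    return HaplogroupNode(
        name=name, markers=markers, token=name, lineage=lineage, collapsed=collapsed
    )


def _node(name: str, markers: list[str], children: list[HaplogroupNode],
          lineage: str | None = None) -> HaplogroupNode:
    return HaplogroupNode(name=name, markers=markers, children=children,
                          lineage=lineage)


def backbone_tree() -> HaplogroupTree:
    """Backbone of the basal MSY tree (markers sorted per branch).

    Deep prior-study markers that define the revised-root structure
    (A1a-T, A2-T stems) carry placeholder names; the node clustering A2
    with A3 carries PK1, the published marker for that grouping.  The
    internal structure of B-M108.1 (2 branches) and B-50f2(P) (8
    branches) is collapsed, as drawn.
    """
    c = _node(
        "C",
        ["M130", "RPS4Y711"],
        [
            _leaf("C1", ["M8"]),
            _node("C2", ["M38"], [_leaf("C2a", ["M208"])]),
            _node("C3", ["M217"], [_leaf("C3a", ["M93"])]),
            _leaf("C4", ["M347"]),
            _leaf("C5", ["M356"]),
            _leaf("C6", ["P55"]),
        ],
    )
    f = _node(
        "F",
        ["M89"],
        [_node("K", ["M9"], [_node("P", ["M45"], [
            _leaf("R", sorted(["M207", "V45", "V69", "V88"]))])])],
    )
    ct = _node(
        "CT",
        ["M168", "M294", "P9.1"],
        [
            _node("DE", ["M1", "M145"], [_leaf("D", ["M174"]), _leaf("E", ["M96"])]),
            _node("CF", ["P143"], [c, f]),
        ],
    )
    b = _node(
        "B",
        ["M60", "M181", "P85", "P90"],
        [
            _leaf("B1", ["M236"]),
            _node(
                "B2",
                ["M182"],
                [
                    _node(
                        "B2a",
                        ["M150"],
                        [
                            _node(
                                "B2a1",
                                ["M218"],
                                [
                                    _leaf("B2a1a", ["M109", "M152"]),
                                    _leaf("B-M108.1", ["M108.1"], collapsed=2),
                                ],
                            )
                        ],
                    ),
                    _node(
                        "B2b",
                        ["M112", "M192"],
                        [_leaf("B-50f2(P)", ["50f2(P)"], collapsed=8)],
                    ),
                    _leaf("B2c", ["Z140"]),
                ],
            ),
        ],
    )
    a3 = _node(
        "A3",
        ["M32"],
        [
            _leaf("A3a", ["M28", "P289"]),
            _node(
                "A3b",
                ["M144"],
                [
                    _node("A3b1", ["M51"], [_leaf("A3b1a", ["P102", "P71"])]),
                    _node(
                        "A3b2",
                        ["M13"],
                        [_leaf("A3b2a", ["M171"]), _leaf("A3b2b", ["M118"])],
                    ),
                ],
            ),
        ],
    )
    a2 = _node(
        "A2",
        ["P3"],
        [
            _leaf("A-M114", ["M114"], lineage="A2a"),
            _leaf("A-P28", ["P28"], lineage="A2b"),
            _leaf("A-P262", ["P262"], lineage="A2c"),
        ],
    )
    root = _node(
        "Root",
        [],
        [
            _leaf("A1b", ["P114"]),
            _node(
                "A1a-T",
                _z(1, 5),
                [
                    _leaf("A1a", ["M31", "P82"]),
                    _node(
                        "A2-T",
                        _z(10, 12),
                        [
                            _node("A2'3", ["PK1"], [a2, a3]),
                            _node("BT", ["M139", "M299", "M42", "M94"], [b, ct]),
                        ],
                    ),
                ],
            ),
        ],
    )
    tree = HaplogroupTree(root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# truth: marker -> derived samples; panel -> typing scope

_A1B_STEM = ["V161"] + _z(101, 118)          # 19 shared by all four
_A1B_N2 = _z(119, 123)
_A1B_N3 = _z(124, 128)
_A1B_TERM = _z(129, 131)                     # join P114 on the terminal branch
A1B_CANDIDATES = _A1B_STEM + _A1B_N2 + _A1B_N3 + _A1B_TERM  # the 32

_A1A_STEM = ["V147"] + _z(500, 515)          # + M31, P82 = 19 shared
_A1A_SPLIT = _z(516, 519)                    # the four distinguishing markers

_A2_STEM = _z(400, 414)
_A2_P262_EXTRA = ["Z415", "Z416"]
_A2_V218 = ["V218", "Z417"]

_A3_STEM = ["V2", "V3", "Z200", "Z201"]
_A3A = ["V11", "Z202"]
_A3B_STEM = ["V33", "V34", "Z203", "Z204"]
_A3B1_STEM = ["V37", "V314", "Z205"]
_A3B1A = ["Z206"]
_A3B1B = ["V262", "V265", "V303"]
_A3B1C = ["Z207", "Z208"]
_A3B2_STEM = ["V317", "Z209"]
_A3B2A = ["Z210"]
_A3B2B = ["Z211"]
_A3B2C = ["V304", "V305", "V306", "V313"]
_A3B2D = ["Z212"]
_A3B2E = ["Z213", "Z214"]

_B_STEM = ["Z300"]
_B2_STEM = ["Z301"]
_B2A_STEM = ["Z302"]
_B2A_CH1 = ["Z303", "Z304"]                  # {s22..s28}
_B2A_CH2 = ["Z305", "Z306"]                  # {s23..s28}
_B2A_CH3 = ["Z307", "Z308"]                  # {s24..s28}
_B2A1_EXTRA = ["Z309"]
_B2A1A_EXTRA = _z(310, 315)

_CT_NEW = _z(600, 606)                       # the seven shared by C, DE and R
_C_STEM_NEW = _z(610, 619)                   # ten of the eleven C-specific
_F_NEW = ["V186", "V205"]


def _truth() -> dict[str, list[str]]:
    """Marker -> samples carrying the derived allele (the encoded truth)."""
    t: dict[str, list[str]] = {}

    def put(markers: list[str], samples: list[str]) -> None:
        for m in markers:
            t[m] = samples

    # backbone clades
    put(["P114"], ["s04"])
    put(_z(1, 5), _s(5, 51))
    put(["M31", "P82"], ["s05", "s06"])
    put(_z(10, 12), _s(7, 51))
    put(["PK1", "V249"], _s(7, 19))
    put(["P3"], _s(7, 9))
    put(["M114", "V73"], ["s07"])
    put(["P28"], [])
    put(["P262"], ["s08", "s09"])
    put(["M32", "P289"], _s(10, 19))
    put(["M28"], ["s10"])
    put(["M144"], _s(11, 19))
    put(["M51"], _s(11, 13))
    put(["P71", "P102"], ["s11"])
    put(["M13"], _s(14, 19))
    put(["M171"], ["s14"])
    put(["M118"], ["s15"])
    put(["M42", "M94", "M139", "M299"], _s(20, 51))
    put(["M60", "M181", "P85", "P90"], _s(20, 32))
    put(["M236"], ["s20"])
    put(["M182"], _s(21, 32))
    put(["M150"], _s(21, 28))
    put(["M218"], _s(26, 28))
    put(["M109", "M152"], ["s27", "s28"])
    put(["M108.1"], ["s26"])
    put(["M112"], _s(29, 32))                # truth: groups B2b with B2c
    put(["M192"], ["s29", "s30"])
    put(["50f2(P)"], ["s30"])
    put(["Z140"], ["s31", "s32"])
    put(["M168", "M294", "P9.1"], _s(33, 51))
    put(_CT_NEW, _s(33, 51))
    put(["M1", "M145"], ["s33"])
    put(["M174"], [])
    put(["M96"], [])
    put(["P143"], _s(34, 51))
    put(["M130", "RPS4Y711"], _s(34, 39))
    put(_C_STEM_NEW, _s(34, 39))
    put(["M8"], ["s34", "s38"])
    put(["M38"], ["s35"])
    put(["M208"], [])
    put(["M217"], ["s36"])
    put(["M93"], [])
    put(["M347"], [])
    put(["M356"], ["s37"])
    put(["P55"], [])
    put(["M89"], _s(40, 51))
    put(_F_NEW, _s(40, 51))
    put(["M9"], _s(42, 51))
    put(["V104"], _s(42, 51))
    put(["M45"], _s(44, 51))
    put(["V231"], _s(44, 51))
    put(["M207", "V45", "V69", "V88"], _s(46, 51))

    # A1b nested chain
    put(_A1B_STEM, _s(1, 4))
    put(_A1B_N2, _s(2, 4))
    put(_A1B_N3, _s(3, 4))
    put(_A1B_TERM, ["s04"])

    # A1a split
    put(_A1A_STEM, ["s05", "s06"])
    put(_A1A_SPLIT, ["s05"])

    # A2
    put(_A2_STEM, _s(7, 9))
    put(_A2_P262_EXTRA, ["s08", "s09"])
    put(_A2_V218, ["s09"])

    # A3
    put(_A3_STEM, _s(10, 19))
    put(_A3A, ["s10"])
    put(_A3B_STEM, _s(11, 19))
    put(_A3B1_STEM, _s(11, 13))
    put(_A3B1A, ["s11"])
    put(_A3B1B, ["s12"])
    put(_A3B1C, ["s13"])
    put(_A3B2_STEM, _s(14, 19))
    put(_A3B2A, ["s14"])
    put(_A3B2B, ["s15"])
    put(_A3B2C, ["s16"])
    put(_A3B2D, ["s17"])
    put(_A3B2E, ["s18"])

    # B
    put(_B_STEM, _s(20, 32))
    put(_B2_STEM, _s(21, 32))
    put(_B2A_STEM, _s(21, 28))
    put(_B2A_CH1, _s(22, 28))
    put(_B2A_CH2, _s(23, 28))
    put(_B2A_CH3, _s(24, 28))
    put(["V341"], ["s25"])
    put(_B2A1_EXTRA, _s(26, 28))
    put(_B2A1A_EXTRA, ["s27", "s28"])
    put(["V254"], ["s28"])

    # C
    put(["V20"], ["s39"])
    put(["V248"], ["s35"])
    put(["V87"], ["s36"])
    return t


def _panels() -> dict[str, PanelSpec]:
    return {
        "A1b": PanelSpec(_s(1, 4), list(A1B_CANDIDATES), ["s05"]),
        "A1a": PanelSpec(["s05", "s06"],
                         ["M31", "P82"] + _A1A_STEM + _A1A_SPLIT, ["s07"]),
        "A2": PanelSpec(
            _s(7, 9),
            ["P3", "M114", "P28", "P262", "V73"]
            + _A2_STEM + _A2_P262_EXTRA + _A2_V218,
            ["s10"],
        ),
        "A3": PanelSpec(
            _s(10, 19),
            ["M32", "M28", "P289", "M144", "M51", "P71", "P102", "M13", "M171",
             "M118"]
            + _A3_STEM + _A3A + _A3B_STEM + _A3B1_STEM + _A3B1A + _A3B1B
            + _A3B1C + _A3B2_STEM + _A3B2A + _A3B2B + _A3B2C + _A3B2D + _A3B2E
            + ["V249"],
            ["s07"],
        ),
        "B": PanelSpec(
            _s(20, 32),
            ["M60", "M181", "P85", "P90", "M236", "M182", "M150", "M218",
             "M109", "M152", "M108.1", "M112", "M192", "50f2(P)", "Z140"]
            + _B_STEM + _B2_STEM + _B2A_STEM + _B2A_CH1 + _B2A_CH2 + _B2A_CH3
            + ["V341"] + _B2A1_EXTRA + _B2A1A_EXTRA + ["V254"],
            ["s33"],
        ),
        "CT": PanelSpec(_s(33, 51), list(_CT_NEW), ["s20"]),
        "C": PanelSpec(_s(34, 39), ["V20", "V248", "V87"] + _C_STEM_NEW, ["s40"]),
        "F": PanelSpec(_s(40, 51), _F_NEW + ["V104", "V231"], ["s34"]),
    }


_SAMPLE_META = (
    [("Y*(xA1a-T)", "Ghana")] * 2
    + [("Y*(xA1a-T)", "Algeria")]
    + [("A1b", "Cameroon")]
    + [("A1a", "Morocco"), ("A1a", "Mali")]
    + [("A-M114", "Namibia"), ("A-P262", "Cameroon"), ("A-P262", "Botswana")]
    + [("A3a", "Ethiopia"), ("A3b1a", "South Africa"), ("A3b1*", "South Africa"),
       ("A3b1*", "Namibia"), ("A3b2a", "Kenya"), ("A3b2b", "Sudan"),
       ("A3b2*", "Ethiopia"), ("A3b2*", "Kenya"), ("A3b2*", "Chad"),
       ("A3b2*", "Sudan")]
    + [("B1", "Mali"), ("B2a*", "Cameroon"), ("B2a*", "Ghana"),
       ("B2a*", "Gabon"), ("B2a*", "Congo"), ("B2a*", "Cameroon"),
       ("B-M108.1", "CAR"), ("B2a1a", "Kenya"), ("B2a1a", "Tanzania"),
       ("B2b*", "Congo"), ("B-50f2(P)", "CAR"), ("B2c", "Cameroon"),
       ("B2c", "Gabon")]
    + [("DE*", "Nigeria")]
    + [("C1", "Japan"), ("C2", "Indonesia"), ("C3", "Mongolia"),
       ("C5", "Pakistan"), ("C1", "Japan"), ("C*", "Italy")]
    + [("F*", "India"), ("F*", "Nepal"), ("K*", "Oceania"), ("K*", "Indonesia"),
       ("P*", "India"), ("P*", "Siberia"),
       ("R", "Italy"), ("R", "Ireland"), ("R", "Iberia"), ("R", "Anatolia"),
       ("R", "Basque"), ("R", "Sardinia")]
)


def _synthetic_positions_catalog(backbone: HaplogroupTree,
                                 truth: dict[str, list[str]]) -> MarkerCatalog:
    """Catalog covering every marker of the fixture.

    Printed markers come from the packaged table with real coordinates;
    everything else gets deterministic synthetic coordinates and default
    A->G alleles (V161 keeps its originally reported G->C orientation so
    the triallelic worked example is faithful).
    """
    catalog = MarkerCatalog()
    for m in new_mutation_table():
        catalog.add(m)
    backbone_markers = set(backbone.all_markers())
    pos = 30_000_000
    for name in sorted(truth):
        if name in catalog:
            continue
        pos += 100
        tag = "backbone" if name in backbone_markers else "prior"
        anc, der = ("G", "C") if name == "V161" else ("A", "G")
        catalog.add(
            Marker(
                name=name,
                positions=(pos,),
                ancestral=anc,
                derived=der,
                mutation_class=SUBSTITUTION,
                source_tag=tag,
                note="synthetic placeholder coordinates",
            )
        )
    return catalog


MANIFEST = """\
Reference-panel fixture manifest
================================
Encoded from the published per-haplogroup panel descriptions and the
redrawn backbone figure; no dataset was deposited, so this fixture is a
synthetic re-expression of the printed statements.

Conventions and reconciliations:
- Marker names with prefix Z are synthetic placeholders for previously
  reported mutations whose branch-by-branch names are not printed
  (including Z140, standing in for the unprinted B2c-defining backbone
  marker).  They are excluded from any count that the text does not
  itself print.
- The B panel types 33 markers in 13 chromosomes, itemized here as 16
  placeholder prior markers + V254 + V341 + 15 backbone markers (the
  printed itemization 17+2+14 cannot be reproduced exactly because the
  B2c marker name is unprinted; the panel-level totals are preserved).
- The A2+A3 clustering node (PK1) is part of the backbone, reflecting
  prior literature; V249 therefore maps as an equivalence with PK1.
- Each panel includes one ancestral control chromosome from the sibling
  clade, encoding polarity knowledge from the discovery sequencing.
- The four distinguishing A1a markers all fall on one of the two split
  branches; the second branch is observed as the paragroup residue.
- Internal structure of B-M108.1 (2 branches) and B-50f2(P) (8 branches)
  is collapsed and excluded from counting, as drawn.
- V161 is encoded with its originally reported G->C orientation in the
  binary matrix; raw alleles (C in the A1b panel, G elsewhere) plus the
  outgroup A drive its decomposition into V161.1/V161.2.
"""


def reference_panel() -> ReferencePanel:
    """Build the full fixture: backbone, catalog, 51-sample matrix, outgroup."""
    backbone = backbone_tree()
    truth = _truth()
    panels = _panels()
    catalog = _synthetic_positions_catalog(backbone, truth)

    samples = [
        SampleRecord(sid, prior_haplogroup=hap, origin=origin)
        for sid, (hap, origin) in zip(_s(1, 51), _SAMPLE_META)
    ]
    all_ids = [s.sample_id for s in samples]

    backbone_markers = set(backbone.all_markers()) | {"V161"}
    typed: dict[str, set[str]] = {}
    for m in truth:
        if m in backbone_markers:
            typed[m] = set(all_ids)
    for spec in panels.values():
        for m in spec.markers:
            typed.setdefault(m, set()).update(spec.samples, spec.controls)
    # V249 joins two panels: typed in the A2 chromosomes as well, with a
    # BT-side ancestral control (it was scored in both mapping rounds)
    typed["V249"].update({"s08", "s09", "s20"})

    marker_order = [m for m in catalog.names() if m in truth]
    calls: dict[str, dict[str, str]] = {sid: {} for sid in all_ids}
    raw: dict[str, dict[str, str]] = {sid: {} for sid in all_ids}
    for m in marker_order:
        derived = set(truth[m])
        for sid in all_ids:
            if sid not in typed[m]:
                calls[sid][m] = NO_CALL
            elif sid in derived:
                calls[sid][m] = DERIVED
            else:
                calls[sid][m] = ANCESTRAL
            if m == "V161" and calls[sid][m] != NO_CALL:
                raw[sid][m] = "C" if sid in derived else "G"

    matrix = GenotypeMatrix.from_calls(
        calls, samples=samples, markers=marker_order, raw_alleles=raw
    )
    outgroup = {
        "V161": OutgroupAllele("V161", "A"),
    }
    return ReferencePanel(backbone, catalog, matrix, outgroup, panels, MANIFEST)


def write_fixture(directory: str | Path) -> dict[str, Path]:
    """Materialize the fixture files (Newick + TSVs) into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    panel = reference_panel()
    paths = {
        "backbone": d / "backbone.nwk",
        "catalog": d / "catalog.tsv",
        "matrix": d / "matrix.tsv",
        "raw_alleles": d / "raw_alleles.tsv",
        "outgroup": d / "outgroup.tsv",
        "manifest": d / "MANIFEST.txt",
    }
    paths["backbone"].write_text(write_newick(panel.backbone))
    paths["catalog"].write_text(write_marker_table(panel.catalog))
    paths["matrix"].write_text(panel.matrix.to_tsv())
    paths["raw_alleles"].write_text(panel.matrix.raw_alleles_to_tsv())
    paths["outgroup"].write_text(write_outgroup_table(panel.outgroup))
    paths["manifest"].write_text(panel.manifest)
    return paths
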