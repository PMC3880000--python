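"""Readers and writers for the package's tab-delimited fixture formats.

All tables are UTF-8 TSV with ``#`` comment lines.  Column layouts:

* karyotype: ``species  chrom  morphology  is_sex``
* homology:  ``target_species  target_chrom  order_index  target_region
  source_species  source_region  alternatives  flags`` — ``target_region``
  is the arm part only (``q``, ``qt``, ``p/qp``, or ``whole``);
  ``source_region`` is a full label token; ``alternatives`` and ``flags``
  are ``|``-joined; gap rows carry ``-`` in both source columns.
* ECU table: ``ecu_id  hsa_segments  mca_chrom  mca_arm``
* trees: newick.

Packaged fixtures encode the published homology table and painting-figure
block order for the MCA -> {GSO, ACU, LCO} comparisons.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .labels import LabelParseError, parse_simple_label
from .model import (
    Chromosome,
    ECU,
    HomologyBlock,
    HomologyMap,
    Karyotype,
    RegionLabel,
    SegmentLabel,
    ValidationError,
    chrom_sort_key,
)

#: source species whose segment labels are opaque (not p/q-arm grammar)
OPAQUE_SOURCE_SPECIES = frozenset({"HSA", "ECU"})

GAP_TOKEN = "-"

KARYOTYPE_COLUMNS = ["species", "chrom", "morphology", "is_sex"]
HOMOLOGY_COLUMNS = [
    "target_species",
    "target_chrom",
    "order_index",
    "target_region",
    "source_species",
    "source_region",
    "alternatives",
    "flags",
]
ECU_COLUMNS = ["ecu_id", "hsa_segments", "mca_chrom", "mca_arm"]


def _read_rows(path: str | Path, columns: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        lines = [l for l in fh if l.strip() and not l.lstrip().startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    if reader.fieldnames is None:
        raise ValidationError(f"{path}: empty file")
    missing = [c for c in columns if c not in reader.fieldnames]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return [dict(row) for row in reader]


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------

def read_karyotype(path: str | Path) -> Karyotype:
    rows = _read_rows(path, KARYOTYPE_COLUMNS)
    if not rows:
        raise ValidationError(f"{path}: no chromosomes")
    species = {r["species"] for r in rows}
    if len(species) != 1:
        raise ValidationError(
            f"{path}: expected one species per file, found {sorted(species)}"
        )
    chroms = [
        Chromosome(
            id=r["chrom"].strip(),
            morphology=r["morphology"].strip(),
            is_sex=r["is_sex"].strip() in ("1", "true", "True"),
        )
        for r in rows
    ]
    return Karyotype(species=species.pop(), chromosomes=tuple(chroms))


def write_karyotype(karyotype: Karyotype, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(KARYOTYPE_COLUMNS)
        for c in karyotype.chromosomes:
            w.writerow(
                [karyotype.species, c.id, c.morphology, int(c.is_sex)]
            )


# ---------------------------------------------------------------------------
# homology maps
# ---------------------------------------------------------------------------

def _parse_target_region(chrom: str, token: str, row_no: int) -> RegionLabel:
    token = token.strip()
    if token in ("", "whole", "."):
        return RegionLabel(chrom)
    try:
        label = parse_simple_label(f"{chrom}{token}")
    except LabelParseError as exc:
        raise ValidationError(
            f"row {row_no}: bad target_region {token!r} on chromosome "
            f"{chrom}: {exc}"
        ) from exc
    return label


def _parse_source(token: str, species: str, row_no: int):
    token = token.strip()
    if species in OPAQUE_SOURCE_SPECIES:
        return SegmentLabel(token)
    try:
        return parse_simple_label(token)
    except LabelParseError as exc:
        raise ValidationError(
            f"row {row_no}: bad source_region {token!r}: {exc}"
        ) from exc


def read_homology(
    path: str | Path,
    probes: set[str] | None = None,
) -> HomologyMap:
    """Read a homology TSV.  Rows may be in any order; they are sorted by
    target chromosome and ``order_index``.  When ``probes`` is given, the
    map must detect every probe chromosome at least once."""
    rows = _read_rows(path, HOMOLOGY_COLUMNS)
    if not rows:
        raise ValidationError(f"{path}: empty homology table")
    target_species = {r["target_species"] for r in rows}
    if len(target_species) != 1:
        raise ValidationError(
            f"{path}: multiple target species {sorted(target_species)}"
        )
    source_species = {
        r["source_species"] for r in rows if r["source_species"] != GAP_TOKEN
    }
    if len(source_species) != 1:
        raise ValidationError(
            f"{path}: expected one source species, found "
            f"{sorted(source_species)}"
        )
    src_sp = source_species.pop()

    blocks: list[HomologyBlock] = []
    for i, r in enumerate(rows, start=2):  # 1-based incl. header line
        chrom = r["target_chrom"].strip()
        try:
            order = int(r["order_index"])
        except ValueError as exc:
            raise ValidationError(
                f"{path} row {i}: bad order_index {r['order_index']!r}"
            ) from exc
        region = _parse_target_region(chrom, r["target_region"], i)
        if (r["source_region"] or "").strip() == GAP_TOKEN:
            source = None
            alts: tuple = ()
        else:
            source = _parse_source(r["source_region"], src_sp, i)
            alts = tuple(
                _parse_source(tok, src_sp, i)
                for tok in (r.get("alternatives") or "").split("|")
                if tok.strip()
            )
        flags = frozenset(
            tok.strip()
            for tok in (r.get("flags") or "").split("|")
            if tok.strip()
        )
        try:
            blocks.append(
                HomologyBlock(
                    target_chrom=chrom,
                    order_index=order,
                    target_region=region,
                    source_region=source,
                    alternatives=alts,
                    flags=flags,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc

    hmap = HomologyMap(
        target_species=target_species.pop(),
        source_species=src_sp,
        blocks=tuple(blocks),
    )
    if probes is not None:
        hmap.validate_probes(probes)
    return hmap


def _region_to_token(block: HomologyBlock) -> str:
    region = block.target_region
    if region.is_whole:
        return "whole"
    return str(region)[len(block.target_chrom):]


def write_homology(hmap: HomologyMap, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(HOMOLOGY_COLUMNS)
        for b in hmap.blocks:
            w.writerow(
                [
                    hmap.target_species,
                    b.target_chrom,
                    b.order_index,
                    _region_to_token(b),
                    GAP_TOKEN if b.is_gap else hmap.source_species,
                    GAP_TOKEN if b.is_gap else str(b.source_region),
                    "|".join(str(a) for a in b.alternatives),
                    "|".join(sorted(b.flags)),
                ]
            )


# ---------------------------------------------------------------------------
# ECU table
# ---------------------------------------------------------------------------

def decompose_hsa_segments(entry: str) -> tuple[str, ...]:
    """Decompose a composite HSA entry (``:`` fusions, ``-`` adjacencies,
    ``+`` splits) into its atomic segment tokens."""
    entry = entry.strip()
    if not entry:
        raise ValidationError("empty ECU token")
    tokens = [t for t in re.split(r"[:+\-]", entry) if t]
    if not tokens:
        raise ValidationError(f"unparseable ECU token {entry!r}")
    for t in tokens:
        if not re.fullmatch(r"\d+[a-z]?|[XY]", t):
            raise ValidationError(
                f"unparseable HSA segment {t!r} in ECU token {entry!r}"
            )
    return tuple(tokens)


def read_ecu_table(path: str | Path) -> list[ECU]:
    rows = _read_rows(path, ECU_COLUMNS)
    grouped: dict[str, dict] = {}
    for r in rows:
        eid = r["ecu_id"].strip()
        entry = grouped.setdefault(
            eid, {"hsa": r["hsa_segments"].strip(), "locs": []}
        )
        if entry["hsa"] != r["hsa_segments"].strip():
            raise ValidationError(
                f"{path}: ECU {eid}: conflicting hsa_segments entries"
            )
        entry["locs"].append((r["mca_chrom"].strip(), r["mca_arm"].strip()))
    ecus = []
    for eid, entry in grouped.items():
        ecus.append(
            ECU(
                ecu_id=eid,
                hsa_segments=entry["hsa"],
                segments=decompose_hsa_segments(entry["hsa"]),
                mca_locations=tuple(entry["locs"]),
            )
        )
    return ecus


def write_ecu_table(ecus: Iterable[ECU], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ECU_COLUMNS)
        for e in ecus:
            for chrom, arm in e.mca_locations:
                w.writerow([e.ecu_id, e.hsa_segments, chrom, arm])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path, outgroup: str | None = None):
    """Read a newick tree; see :class:`karyopaint.phylo.PhylogeneticTree`."""
    from .phylo import PhylogeneticTree

    return PhylogeneticTree.from_newick(
        Path(path).read_text(encoding="utf-8"), outgroup=outgroup
    )


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = [
    "karyotype_MCA.tsv",
    "karyotype_GSO.tsv",
    "karyotype_ACU.tsv",
    "karyotype_LCO.tsv",
    "homology_GSO_from_MCA.tsv",
    "homology_ACU_from_MCA.tsv",
    "homology_LCO_from_MCA.tsv",
    "homology_GSO_to_HSA.tsv",
    "ecu.tsv",
    "tree.nwk",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture."""
    ref = resources.files("karyopaint.data").joinpath(name)
    return Path(str(ref))


def fixture_checksum(name: str) -> str:
    return hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()


@dataclass(frozen=True)
class PaperDataset:
    """All packaged in-paper fixtures, parsed and validated."""

    karyotypes: dict[str, Karyotype]
    maps: dict[str, HomologyMap]  # target species -> map from MCA
    gso_to_hsa: HomologyMap
    ecus: list[ECU]
    tree: object  # PhylogeneticTree

    @property
    def probe_autosomes(self) -> set[str]:
        return {
            c.id for c in self.karyotypes["MCA"].chromosomes if not c.is_sex
        }


def load_paper_dataset() -> PaperDataset:
    karyotypes = {
        sp: read_karyotype(fixture_path(f"karyotype_{sp}.tsv"))
        for sp in ("MCA", "GSO", "ACU", "LCO")
    }
    probes = {
        c.id
        for c in karyotypes["MCA"].chromosomes
        if not c.is_sex or c.id == "X"  # no Y paint was used
    }
    maps = {
        sp: read_homology(
            fixture_path(f"homology_{sp}_from_MCA.tsv"), probes=probes
        )
        for sp in ("GSO", "ACU", "LCO")
    }
    gso_to_hsa = read_homology(fixture_path("homology_GSO_to_HSA.tsv"))
    ecus = read_ecu_table(fixture_path("ecu.tsv"))
    tree = read_tree(fixture_path("tree.nwk"), outgroup="MCA")
    return PaperDataset(
        karyotypes=karyotypes,
        maps=maps,
        gso_to_hsa=gso_to_hsa,
        ecus=ecus,
        tree=tree,
    )
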