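"""Analysis orchestration: run the full painting-comparison pipeline over
a dataset and assemble a deterministic, machine-readable report.

Every number in the report is produced by the underlying operation —
counts are cardinalities of the sets also included, never report-local
arithmetic.  Re-running on identical inputs yields byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .io import (
    FIXTURE_NAMES,
    PaperDataset,
    fixture_checksum,
    load_paper_dataset,
)
from .model import ValidationError
from .phylo import (
    PhylogeneticTree,
    annotated_newick,
    build_character_matrix,
    place_paper_rule,
)
from .synteny import (
    AssociationProfile,
    compose_homology,
    identity_homology,
    compute_fundamental_number,
    count_conserved_regions,
    ecu_disruption_count,
    extract_syntenic_associations,
    infer_plesiomorphic_chromosomes,
    mca_ecu_lookup,
    shared_associations,
)

log = logging.getLogger("karyopaint")


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    diploid_number: int
    fundamental_number: int
    conserved_regions: int
    intact: tuple[str, ...]
    associations: tuple[str, ...]
    ambiguous_associations: tuple[str, ...]
    disrupted_ecus: tuple[str, ...]


@dataclass(frozen=True)
class AnalysisReport:
    species: dict[str, SpeciesSummary]
    shared: dict[str, tuple[str, ...]]
    plesiomorphic: tuple[str, ...]
    placements: dict
    annotated_tree: str
    fixture_checksums: dict[str, str]
    version: str

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "fixture_checksums": dict(sorted(self.fixture_checksums.items())),
            "species": {
                sp: {
                    "2n": s.diploid_number,
                    "FN": s.fundamental_number,
                    "conserved_regions": s.conserved_regions,
                    "intact": list(s.intact),
                    "intact_count": len(s.intact),
                    "associations": list(s.associations),
                    "association_count": len(s.associations),
                    "ambiguous_associations": list(s.ambiguous_associations),
                    "disrupted_ecus": list(s.disrupted_ecus),
                    "disrupted_ecu_count": len(s.disrupted_ecus),
                }
                for sp, s in sorted(self.species.items())
            },
            "shared_associations": {
                k: list(v) for k, v in sorted(self.shared.items())
            },
            "plesiomorphic_chromosomes": list(self.plesiomorphic),
            "plesiomorphic_count": len(self.plesiomorphic),
            "placements": self.placements,
            "annotated_tree": self.annotated_tree,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _sorted_assoc(assocs) -> tuple[str, ...]:
    return tuple(sorted(a.canonical_name for a in assocs))


def _chrom_sorted(chroms) -> tuple[str, ...]:
    from .model import chrom_sort_key

    return tuple(sorted(chroms, key=chrom_sort_key))


def run_analysis(dataset: PaperDataset | None = None) -> AnalysisReport:
    """Run the full comparison pipeline and assemble the report."""
    data = dataset or load_paper_dataset()
    probes = data.probe_autosomes
    lookup = mca_ecu_lookup(data.ecus)
    tree: PhylogeneticTree = data.tree

    outgroup = "MCA"
    profiles: list[AssociationProfile] = []
    species_summaries: dict[str, SpeciesSummary] = {}
    for sp, karyotype in data.karyotypes.items():
        if sp == outgroup:
            # the probe species maps onto itself: identity map
            hmap = identity_homology(karyotype)
            disrupted: list[str] = []
        else:
            hmap = data.maps[sp]
        profile = extract_syntenic_associations(hmap)
        profiles.append(profile)
        if sp != outgroup:
            composed = compose_homology(hmap, lookup)
            _, disrupted = ecu_disruption_count(composed, data.ecus)
        species_summaries[sp] = SpeciesSummary(
            species=sp,
            diploid_number=karyotype.diploid_number,
            fundamental_number=compute_fundamental_number(karyotype),
            conserved_regions=count_conserved_regions(hmap, probes=probes),
            intact=_chrom_sorted(profile.intact),
            associations=_sorted_assoc(profile.associations),
            ambiguous_associations=_sorted_assoc(profile.ambiguous),
            disrupted_ecus=tuple(disrupted),
        )
        log.info(
            "%s: %d conserved regions, %d intact, %d associations",
            sp,
            species_summaries[sp].conserved_regions,
            len(profile.intact),
            len(profile.associations),
        )

    shared = {
        "GSO+ACU+LCO": _sorted_assoc(
            shared_associations(profiles, required={"GSO", "ACU", "LCO"})
        ),
        "ACU+GSO-not-LCO": _sorted_assoc(
            shared_associations(
                profiles, required={"ACU", "GSO"}, excluded={"LCO"}
            )
        ),
        "ACU+LCO-not-GSO": _sorted_assoc(
            shared_associations(
                profiles, required={"ACU", "LCO"}, excluded={"GSO"}
            )
        ),
    }
    plesiomorphic = _chrom_sorted(
        infer_plesiomorphic_chromosomes(profiles, outgroup=outgroup)
    )
    matrix = build_character_matrix(profiles, outgroup=outgroup)
    placement_report = place_paper_rule(tree, matrix)
    checksums = {}
    for name in FIXTURE_NAMES:
        try:
            checksums[name] = fixture_checksum(name)
        except FileNotFoundError:
            pass
    return AnalysisReport(
        species=species_summaries,
        shared=shared,
        plesiomorphic=plesiomorphic,
        placements=placement_report.to_dict(),
        annotated_tree=annotated_newick(tree, placement_report),
        fixture_checksums=checksums,
        version=__version__,
    )


def write_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(report.to_json(), encoding="utf-8")
    return path


def homology_table_tsv(data: PaperDataset) -> str:
    """TSV mirror of the published homology table: one row per MCA region
    with its homologs in ACU, LCO and GSO and the ECU entry."""
    lines = ["MCA\tACU\tLCO\tGSO\tECUs"]
    locations: dict[tuple[str, str], dict[str, list[str]]] = {}
    for sp in ("ACU", "LCO", "GSO"):
        for b in data.maps[sp].blocks:
            if b.is_gap or b.source_chrom in ("X", "Y"):
                continue
            region = b.source_region
            arm = region.arm if not region.is_whole else "whole"
            key = (b.source_chrom, arm)
            entry = str(b.target_region)
            if b.alternatives:
                entry += " or " + "|".join(str(a) for a in b.alternatives)
            locations.setdefault(key, {}).setdefault(sp, []).append(entry)
    ecu_by_loc = {
        loc: e.hsa_segments for e in data.ecus for loc in e.mca_locations
    }
    for (chrom, arm), per_sp in sorted(
        locations.items(), key=lambda kv: (int(kv[0][0]), kv[0][1])
    ):
        mca_label = chrom if arm == "whole" else f"{chrom}{arm}"
        row = [mca_label]
        for sp in ("ACU", "LCO", "GSO"):
            row.append(" + ".join(per_sp.get(sp, [])))
        row.append(ecu_by_loc.get((chrom, arm), ""))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
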