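"""End-to-end convenience: scenario directory -> calls -> candidate genes."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import yaml

from .fragmap import (
    BaitSpec,
    CVIQI,
    DPNII,
    EnzymeSpec,
    FragmentMap,
    ReferenceSet,
    read_fragment_map,
)
from .fourc import (
    FragmentCoverage,
    InteractionCall,
    call_interactions,
    process_fastq,
    summarize_cis_trans,
)
from .integrate import CandidateGene, DERecord, nominate_targets, read_de_table


@dataclass
class PipelineResult:
    coverages: List[FragmentCoverage]
    calls: List[InteractionCall]
    candidates: List[CandidateGene]
    bait: BaitSpec
    fragmap: FragmentMap
    de_records: List[DERecord]


def run_from_scenario_dir(
    scenario_dir,
    rpm_threshold: float = 50.0,
    window: int = 50_000,
    fc_cut: float = 1.3,
    padj_cut: float = 0.05,
    enzymes: Sequence[EnzymeSpec] = (DPNII, CVIQI),
) -> PipelineResult:
    """Run the full chain from the files a scenario directory contains.

    Reads the manifest, processes each replicate FASTQ pair to fragment
    coverage, calls reproducible interactions, and nominates target genes
    against the DE table.
    """
    scenario_dir = Path(scenario_dir)
    with open(scenario_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    refs = ReferenceSet.from_fasta(scenario_dir / manifest["paths"]["genome_fasta"])
    fragmap = read_fragment_map(scenario_dir / manifest["paths"]["fragment_map_bed"])
    b = manifest["bait"]
    bait = BaitSpec(
        chrom=b["chrom"],
        position=b["position"],
        reading_primer=b["reading_primer"],
        exclusion_radius_fragments=b.get("exclusion_radius_fragments", 2),
    ).resolve(fragmap)

    coverages: List[FragmentCoverage] = []
    for rep, (fq1, fq2) in sorted(manifest["paths"]["fastq"].items()):
        coverages.append(
            process_fastq(
                scenario_dir / fq1, scenario_dir / fq2,
                refs, bait, fragmap, enzymes, replicate_id=rep,
            )
        )
    calls = call_interactions(coverages, bait, fragmap, rpm_threshold=rpm_threshold)
    de_records = read_de_table(scenario_dir / manifest["paths"]["de_table"])
    candidates = nominate_targets(
        de_records, calls,
        fc_cut=fc_cut, padj_cut=padj_cut, rpm_cut=rpm_threshold, window=window,
    )
    return PipelineResult(
        coverages=coverages, calls=calls, candidates=candidates,
        bait=bait, fragmap=fragmap, de_records=de_records,
    )
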