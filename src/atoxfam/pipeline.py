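"""End-to-end pipeline: screen -> family filter -> align -> distances ->
NJ -> bootstrap -> consensus -> signatures.

Every sequence appearing in any downstream artifact has passed both the
seven-TM hydropathy screen and the family-motif filter (the family's
inclusion rule).  All stochastic steps are seeded, and the run log records
the seed, parameters and input digest, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import Alignment, write_aligned_fasta
from .family_motif import DEFAULT_PATTERN, find_family_motif, variant_counts
from .msa import blosum62_scheme, build_guide_tree, progressive_align
from .phylo import bootstrap_trees, majority_consensus, nj_tree, poisson_distance_matrix
from .seqio import GroupLabeling, ProteinSequence, fasta_string, read_fasta, read_group_table
from .signatures import annotate_motif_region, mine_signatures, signature_report
from .topology import TopologyParams, screen_seven_tm

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    fasta: Path | None = None
    labels: Path | None = None
    outdir: Path = Path("atoxfam_out")
    topology: TopologyParams = field(default_factory=TopologyParams)
    motif_pattern: str = DEFAULT_PATTERN
    gap_open: int = -10
    gap_extend: int = -1
    deletion: str = "pairwise"
    bootstrap_reps: int = 1000
    bootstrap_seed: int = 0
    consensus_cutoff: float = 50.0
    signature_len_bounds: tuple[int, int] = (6, 25)
    min_group_size: int = 2


@dataclass
class PipelineResult:
    screened: pd.DataFrame
    kept: list[ProteinSequence]
    alignment: Alignment
    nj: object
    consensus: object
    signatures: pd.DataFrame
    artifacts: dict[str, Path]


def run_pipeline(
    cfg: PipelineConfig,
    seqs: list[ProteinSequence] | None = None,
    labels: GroupLabeling | None = None,
) -> PipelineResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("atoxfam")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"run_log": log_path}
    try:
        if seqs is None:
            if cfg.fasta is None:
                raise PipelineError("input: no FASTA given")
            with open(cfg.fasta) as fh:
                seqs = read_fasta(fh)
        if labels is None and cfg.labels is not None:
            with open(cfg.labels) as fh:
                labels = read_group_table(fh)
            labels.validate_against(seqs)
        digest = hashlib.sha256(
            "".join(s.id + s.residues for s in seqs).encode()
        ).hexdigest()[:16]
        log.info("atoxfam %s", __version__)
        log.info("input: %d sequences, digest %s", len(seqs), digest)
        log.info("params: %s", dataclasses.asdict(cfg))

        # stage 1: topology screen + family-motif filter
        rows = []
        kept: list[ProteinSequence] = []
        topos = {}
        motifs = {}
        for s in seqs:
            ok, topo = screen_seven_tm(s, cfg.topology)
            match = None
            if ok and topo is not None:
                match = find_family_motif(s, topo, cfg.motif_pattern)
            keep = ok and match is not None
            rows.append(
                {
                    "id": s.id,
                    "seven_tm": ok,
                    "family_motif": match.variant if match else "",
                    "kept": keep,
                    "segments": ";".join(
                        f"{a}-{b}" for a, b in (topo.tm_segments if topo else [])
                    ),
                }
            )
            if keep:
                kept.append(s)
                topos[s.id] = topo
                motifs[s.id] = match
        screened = pd.DataFrame(rows)
        screened.to_csv(outdir / "screen_report.tsv", sep="\t", index=False)
        artifacts["screen_report"] = outdir / "screen_report.tsv"
        log.info("screen: %d of %d sequences kept", len(kept), len(seqs))
        if not kept:
            raise PipelineError("screen: no sequences passed family screen")
        (outdir / "filtered.fasta").write_text(fasta_string(kept))
        artifacts["filtered_fasta"] = outdir / "filtered.fasta"
        counts = variant_counts([motifs[s.id] for s in kept])
        pd.DataFrame(
            [{"variant": v, "count": c} for v, c in counts.items()]
        ).to_csv(outdir / "family_motifs.tsv", sep="\t", index=False)
        artifacts["family_motifs"] = outdir / "family_motifs.tsv"

        # stage 2: alignment
        try:
            scheme = blosum62_scheme(cfg.gap_open, cfg.gap_extend)
            guide = build_guide_tree(kept, scheme) if len(kept) > 1 else None
            aln = progressive_align(kept, guide, scheme)
        except Exception as exc:
            raise PipelineError(f"align: {exc}") from exc
        with open(outdir / "aligned.fasta", "w") as fh:
            write_aligned_fasta(aln, fh)
        artifacts["aligned_fasta"] = outdir / "aligned.fasta"

        # stage 3: distances + NJ + bootstrap + consensus
        try:
            dm = poisson_distance_matrix(aln, deletion=cfg.deletion)
            pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(
                outdir / "distances.tsv", sep="\t"
            )
            artifacts["distances"] = outdir / "distances.tsv"
            nj = nj_tree(dm)
            (outdir / "nj_tree.nwk").write_text(nj.to_newick() + "\n")
            artifacts["nj_tree"] = outdir / "nj_tree.nwk"
            reps = bootstrap_trees(
                aln, cfg.bootstrap_reps, cfg.bootstrap_seed, deletion=cfg.deletion
            )
            consensus = majority_consensus(reps, cfg.consensus_cutoff)
            (outdir / "consensus_tree.nwk").write_text(
                consensus.to_newick(lengths=False) + "\n"
            )
            artifacts["consensus_tree"] = outdir / "consensus_tree.nwk"
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"tree: {exc}") from exc

        # stage 4: signatures
        sig_rows = []
        if labels is not None:
            for group in sorted(labels.groups()):
                if len(labels.members(group) & set(aln.ids)) == len(aln.ids):
                    continue  # whole-dataset groups cannot be specific
                found = mine_signatures(
                    aln, labels, group,
                    len_bounds=cfg.signature_len_bounds,
                    min_group_size=cfg.min_group_size,
                )
                for m in found:
                    members = sorted(labels.members(group) & set(aln.ids))
                    if all(i in topos for i in members):
                        annotate_motif_region(m, topos, aln, members)
                sig_rows.extend(found)
        signatures = signature_report(sig_rows)
        signatures.to_csv(outdir / "signatures.tsv", sep="\t", index=False)
        artifacts["signatures"] = outdir / "signatures.tsv"
        log.info("signatures: %d motifs reported", len(signatures))
        return PipelineResult(
            screened=screened,
            kept=kept,
            alignment=aln,
            nj=nj,
            consensus=consensus,
            signatures=signatures,
            artifacts=artifacts,
        )
    finally:
        root_logger.removeHandler(handler)
        handler.close()
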