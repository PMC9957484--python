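"""End-to-end orchestration: genome -> repeats -> conformation references ->
read support -> frequencies -> isomer predictions -> MTPT report."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .conformation_builder import DEFAULT_FLANK_LEN, build_conformation_refs
from .errors import MitorecombError, NoSupportError
from .genome_model import GenomeSet, Read
from .isomer_predictor import MoleculeSet, predict_products
from .mtpt_finder import (
    DEFAULT_EVALUE,
    DEFAULT_MIN_LENGTH as MTPT_MIN_LENGTH,
    find_mtpts,
    summarize_mtpts,
)
from .read_classifier import ClassificationParams, compute_frequencies, count_support
from .repeat_finder import (
    DEFAULT_MIN_IDENTITY,
    DEFAULT_MIN_LENGTH,
    RepeatPair,
    find_repeat_pairs,
)

__all__ = ["PipelineParams", "RunReport", "run_all", "write_frequency_tsv"]

log = logging.getLogger("mitorecomb")


@dataclass(frozen=True)
class PipelineParams:
    min_length: int = DEFAULT_MIN_LENGTH
    min_identity: float = DEFAULT_MIN_IDENTITY
    flank_len: int = DEFAULT_FLANK_LEN
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    evalue_threshold: float = DEFAULT_EVALUE
    mtpt_min_length: int = MTPT_MIN_LENGTH


@dataclass
class RunReport:
    version: str
    parameters: dict
    genome: dict
    rows: list[dict]  # per repeat pair: Table-3-style row
    isomers: list[dict]
    mtpt: dict | None
    checksums: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage(name: str, **info) -> None:
    log.info("%s: %s", name, ", ".join(f"{k}={v}" for k, v in info.items()))


def sha256_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _pair_row(genome: GenomeSet, pair: RepeatPair, reads, params: PipelineParams) -> dict:
    refs = build_conformation_refs(genome, pair, params.flank_len)
    counts = count_support(reads, refs, params.classification)
    row = {
        "id": pair.id,
        "length": pair.length,
        "identity": pair.identity,
        "orientation": pair.orientation.value,
        "size_class": pair.size_class.value,
        "position": pair.position_text(),
        "m1": counts.m1,
        "m2": counts.m2,
        "a1": counts.a1,
        "a2": counts.a2,
        "ambiguous": counts.ambiguous,
        "unclassified": counts.unclassified,
        "major_fraction": None,
        "alternative_fraction": None,
        "flags": sorted({f for r in refs.values() for f in r.flags}),
    }
    try:
        freq = compute_frequencies(counts)
        row["major_fraction"] = freq.major
        row["alternative_fraction"] = freq.alternative
    except NoSupportError:
        pass
    return row


def run_all(
    genome: GenomeSet,
    reads: list[Read],
    cp: GenomeSet | None = None,
    params: PipelineParams | None = None,
    checksums: dict | None = None,
) -> RunReport:
    """Run every stage on in-memory inputs; deterministic for fixed inputs.

    The MTPT section is present only when a chloroplast genome is given.
    """
    params = params or PipelineParams()
    try:
        _stage("find_repeats", chromosomes=len(genome), total_bp=genome.total_length,
               min_length=params.min_length, min_identity=params.min_identity)
        pairs = find_repeat_pairs(genome, params.min_length, params.min_identity)
        _stage("classify_reads", pairs=len(pairs), reads=len(reads),
               flank_len=params.flank_len)
        rows = [_pair_row(genome, p, reads, params) for p in pairs]
        _stage("predict_products", pairs=len(pairs))
        stubs = MoleculeSet.from_lengths({c.id: c.length for c in genome})
        isomers = []
        for pair in pairs:
            products = predict_products(stubs, pair, mode="lengths")
            isomers.append(
                {
                    "pair_id": pair.id,
                    "provenance": products.provenance,
                    "products": [
                        {"id": m.id, "length": m.length} for m in products.molecules
                    ],
                    "total_length": products.total_length,
                }
            )
        mtpt_section = None
        if cp is not None:
            _stage("find_mtpt", cp_bp=cp.total_length,
                   evalue=params.evalue_threshold)
            hits = find_mtpts(
                genome, cp,
                evalue_threshold=params.evalue_threshold,
                min_length=params.mtpt_min_length,
            )
            summary = summarize_mtpts(hits, genome.total_length)
            mtpt_section = {
                "hits": [
                    {
                        "mt_chrom": h.mt_interval.chrom,
                        "mt_start": h.mt_interval.start + 1,
                        "mt_end": h.mt_interval.end,
                        "cp_chrom": h.cp_interval.chrom,
                        "cp_start": h.cp_interval.start + 1,
                        "cp_end": h.cp_interval.end,
                        "cp_strand": h.cp_interval.strand.value,
                        "length": h.length,
                        "identity": h.identity,
                        "e_value": h.e_value,
                    }
                    for h in hits
                ],
                "count": summary.count,
                "total_bp": summary.total_bp,
                "percent": summary.percent,
            }
    except MitorecombError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise MitorecombError(f"pipeline failed: {exc}") from exc

    return RunReport(
        version=__version__,
        parameters={
            "min_length": params.min_length,
            "min_identity": params.min_identity,
            "flank_len": params.flank_len,
            "min_anchor": params.classification.min_anchor,
            "max_error_rate": params.classification.max_error_rate,
            "min_identity_margin": params.classification.min_identity_margin,
            "evalue_threshold": params.evalue_threshold,
            "mtpt_min_length": params.mtpt_min_length,
        },
        genome={
            "chromosomes": [
                {"id": c.id, "length": c.length, "topology": c.topology.value}
                for c in genome
            ],
            "total_length": genome.total_length,
            "gc_content": round(genome.gc_content, 4) if genome.total_length else None,
        },
        rows=rows,
        isomers=isomers,
        mtpt=mtpt_section,
        checksums=checksums or {},
    )


_FREQ_COLS = [
    "id", "length", "identity", "position", "m1", "m2", "a1", "a2",
    "major_fraction", "alternative_fraction", "ambiguous", "unclassified",
]


def write_frequency_tsv(rows: list[dict], path: str | os.PathLike) -> None:
    """Table-3-style TSV plus ambiguous/unclassified columns."""

    def fmt(v) -> str:
        if v is None:
            return "NA"
        if isinstance(v, float):
            return f"{v:.4f}" if v != int(v) or 0 < v < 1 else f"{v:g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(_FREQ_COLS) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(row[c]) for c in _FREQ_COLS) + "\n")
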