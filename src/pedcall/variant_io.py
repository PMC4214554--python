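"""Likelihood input/output: VCF with FORMAT/PL, and a likelihood-only
tab-separated table for data from platforms that do not produce VCF.

The table dialect (defined by this project, documented here and in the
README)::

    #chrom  pos  id  ref  alt  <sample>_RR  <sample>_RA  <sample>_AA  ...

one column triple per sample, likelihoods on linear scale, ``.`` for a
missing id/alt.  Output files preserve every input record and append,
for each sequenced pedigree member, the individual-based and
family-based called genotype and its posterior probability
(GPI/PPI/GPF/PPF, posteriors printed with 4 decimal places).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .errors import MalformedPLError, MissingPLError, SampleMismatchError, VariantIOError
from .evidence import PosteriorCall, uniform_likelihoods
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

GT_STRINGS = ("0/0", "0/1", "1/1")
#: PL value standing in for a zero likelihood when encoding
MAX_PL = 99999

_FORMAT_HEADER_LINES = (
    '##FORMAT=<ID=GPI,Number=1,Type=String,Description='
    '"Called genotype, individual-based (likelihood x prior)">',
    '##FORMAT=<ID=PPI,Number=1,Type=String,Description='
    '"Posterior probability of GPI, individual-based">',
    '##FORMAT=<ID=GPF,Number=1,Type=String,Description='
    '"Called genotype, family-based (pedigree-marginalised posterior)">',
    '##FORMAT=<ID=PPF,Number=1,Type=String,Description='
    '"Posterior probability of GPF, family-based">',
)


@dataclass(eq=False)
class VariantRecord:
    """One candidate (or skipped) site with per-member likelihoods.

    ``likelihoods`` is (n_members, 3) on linear scale, aligned to
    pedigree member order, uniform rows for unsequenced members and
    samples with missing PL; ``None`` for non-candidate records.
    ``source`` keeps the original record for pass-through output.
    """

    chrom: str
    pos: int
    vid: str | None
    ref: str
    alts: tuple[str, ...]
    is_dbsnp: bool
    candidate: bool
    skip_reason: str | None
    likelihoods: np.ndarray | None
    source: object
    source_format: str  # "vcf" | "table"
    table_samples: tuple[str, ...] | None = None


def pl_to_likelihood(pl: Sequence[int]) -> np.ndarray:
    """Linear-scale likelihoods 10^(-PL/10) from a Phred-scaled triple."""
    arr = np.asarray(pl, dtype=float)
    if arr.shape != (3,):
        raise MalformedPLError(f"PL must have 3 entries, got {list(pl)!r}")
    if np.any(arr < 0):
        raise MalformedPLError(f"negative PL entry in {list(pl)!r}")
    return 10.0 ** (-arr / 10.0)


def likelihood_to_pl(lik: Sequence[float]) -> tuple[int, int, int]:
    """Phred-scale a likelihood triple, min-shifted so the best genotype
    gets PL 0 and rounded to integers (inverse of :func:`pl_to_likelihood`
    on integer PLs)."""
    arr = np.asarray(lik, dtype=float)
    if arr.shape != (3,) or np.any(arr < 0) or arr.max() <= 0:
        raise MalformedPLError(f"invalid likelihood triple {list(lik)!r}")
    with np.errstate(divide="ignore"):
        pl = -10.0 * np.log10(arr)
    pl = pl - pl.min()
    pl = np.where(np.isfinite(pl), pl, MAX_PL)
    return tuple(int(x) for x in np.rint(np.minimum(pl, MAX_PL)))


def _n_pl_entries(n_alts: int) -> int:
    n_alleles = n_alts + 1
    return n_alleles * (n_alleles + 1) // 2


def _vcf_record(rec: pysam.VariantRecord, ped: Pedigree, first_alt: bool) -> VariantRecord:
    alts = tuple(rec.alts) if rec.alts else ()
    candidate = True
    reason = None
    if not alts:
        candidate, reason = False, "no alternative allele"
    elif len(alts) > 1 and not first_alt:
        candidate, reason = False, "multi-allelic site"
        logger.warning(
            "skipping multi-allelic site %s:%d (use first_alt to call it)",
            rec.chrom,
            rec.pos,
        )
    lik = None
    if candidate:
        expected = _n_pl_entries(len(alts))
        lik = uniform_likelihoods(ped.n)
        for name, i in ped.sequenced_index.items():
            pl = rec.samples[name].get("PL")
            if pl is None or all(x is None for x in pl):
                continue  # missing PL: uninformative at this site only
            if len(pl) != expected:
                raise MalformedPLError(
                    f"{rec.chrom}:{rec.pos} sample {name}: expected {expected} "
                    f"PL entries, got {len(pl)}"
                )
            triple = pl[:3]  # 0/0, 0/1, 1/1 w.r.t. the first ALT
            if any(x is None for x in triple):
                continue
            lik[i] = pl_to_likelihood(triple)
    return VariantRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        vid=rec.id,
        ref=rec.ref,
        alts=alts,
        is_dbsnp=rec.id is not None,
        candidate=candidate,
        skip_reason=reason,
        likelihoods=lik,
        source=rec,
        source_format="vcf",
    )


def read_vcf(
    path: str | Path, ped: Pedigree, first_alt: bool = False
) -> Iterator[VariantRecord]:
    """Stream records from a VCF, matching sample columns to the pedigree
    by sample name.  dbSNP membership is taken from the ID field."""
    vf = pysam.VariantFile(str(path))
    if "PL" not in vf.header.formats:
        raise MissingPLError(f"{path}: VCF FORMAT does not define PL")
    header_samples = set(vf.header.samples)
    missing = sorted(s for s in ped.sequenced_index if s not in header_samples)
    if missing:
        raise SampleMismatchError(
            f"{path}: sequenced pedigree members missing from VCF: {missing}"
        )
    for rec in vf:
        yield _vcf_record(rec, ped, first_alt)


def read_likelihood_table(path: str | Path, ped: Pedigree) -> Iterator[VariantRecord]:
    """Stream records from the likelihood-only table format."""
    fh = open(path)
    try:
        header = None
        for line in fh:
            if line.strip():
                header = line.rstrip("\n")
                break
        if header is None or not header.startswith("#"):
            raise VariantIOError(f"{path}: missing '#'-prefixed header row")
        cols = header.lstrip("#").split()
        if len(cols) < 5:
            raise VariantIOError(f"{path}: header needs at least 5 fixed columns")
        samples: list[str] = []
        i = 5
        while i + 3 <= len(cols) and cols[i].endswith("_RR"):
            base = cols[i][:-3]
            if cols[i + 1] != f"{base}_RA" or cols[i + 2] != f"{base}_AA":
                raise VariantIOError(
                    f"{path}: sample columns must come in {base}_RR/_RA/_AA triples"
                )
            samples.append(base)
            i += 3
        # any remaining columns (e.g. appended result columns) are ignored
        n_lik_cols = 5 + 3 * len(samples)
        missing = sorted(s for s in ped.sequenced_index if s not in samples)
        if missing:
            raise SampleMismatchError(
                f"{path}: sequenced pedigree members missing from table: {missing}"
            )
        col_of = {s: 5 + 3 * j for j, s in enumerate(samples)}
        sample_tuple = tuple(samples)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < n_lik_cols:
                raise VariantIOError(
                    f"{path}:{lineno}: expected at least {n_lik_cols} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos_s, vid, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as e:
                raise VariantIOError(f"{path}:{lineno}: bad position {pos_s!r}") from e
            candidate = alt != "."
            lik = None
            if candidate:
                lik = uniform_likelihoods(ped.n)
                for name, k in ped.sequenced_index.items():
                    j = col_of[name]
                    try:
                        triple = np.array([float(x) for x in fields[j : j + 3]])
                    except ValueError as e:
                        raise VariantIOError(
                            f"{path}:{lineno}: non-numeric likelihood for {name}"
                        ) from e
                    if np.any(triple < 0) or triple.max() <= 0:
                        raise VariantIOError(
                            f"{path}:{lineno}: likelihood triple for {name} must be "
                            "non-negative with at least one positive entry"
                        )
                    lik[k] = triple
            yield VariantRecord(
                chrom=chrom,
                pos=pos,
                vid=None if vid == "." else vid,
                ref=ref,
                alts=() if alt == "." else (alt,),
                is_dbsnp=vid != ".",
                candidate=candidate,
                skip_reason=None if candidate else "no alternative allele",
                likelihoods=lik,
                source=fields[:n_lik_cols],
                source_format="table",
                table_samples=sample_tuple,
            )
    finally:
        fh.close()


class VcfWriter:
    """Append GPI/PPI/GPF/PPF FORMAT fields to a VCF, preserving records."""

    def __init__(self, path: str | Path, template_header: pysam.VariantHeader):
        header = template_header.copy()
        for line in _FORMAT_HEADER_LINES:
            key = line.split("ID=")[1].split(",")[0]
            if key not in header.formats:
                header.add_line(line)
        self.header = header
        self._vf = pysam.VariantFile(str(path), "w", header=header)

    def write_site(
        self,
        record: VariantRecord,
        ped: Pedigree,
        individual: PosteriorCall | None,
        family: PosteriorCall | None,
    ) -> None:
        rec: pysam.VariantRecord = record.source
        rec.translate(self.header)
        if record.candidate and individual is not None and family is not None:
            for name, i in ped.sequenced_index.items():
                sample = rec.samples[name]
                sample["GPI"] = GT_STRINGS[individual.genotypes[i]]
                sample["PPI"] = f"{individual.called_probability(i):.4f}"
                sample["GPF"] = GT_STRINGS[family.genotypes[i]]
                sample["PPF"] = f"{family.called_probability(i):.4f}"
        self._vf.write(rec)

    def close(self) -> None:
        self._vf.close()


class TableWriter:
    """Append per-sample result columns to a likelihood-only table."""

    def __init__(self, path: str | Path, samples: Sequence[str]):
        self.samples = tuple(samples)
        self._fh = open(path, "w")
        cols = ["#chrom", "pos", "id", "ref", "alt"]
        for s in self.samples:
            cols += [f"{s}_RR", f"{s}_RA", f"{s}_AA"]
        for s in self.samples:
            cols += [f"{s}_GPI", f"{s}_PPI", f"{s}_GPF", f"{s}_PPF"]
        self._fh.write("\t".join(cols) + "\n")

    def write_site(
        self,
        record: VariantRecord,
        ped: Pedigree,
        individual: PosteriorCall | None,
        family: PosteriorCall | None,
    ) -> None:
        fields = list(record.source)
        for s in self.samples:
            i = ped.sequenced_index.get(s)
            if (
                i is None
                or not record.candidate
                or individual is None
                or family is None
            ):
                fields += [".", ".", ".", "."]
            else:
                fields += [
                    GT_STRINGS[individual.genotypes[i]],
                    f"{individual.called_probability(i):.4f}",
                    GT_STRINGS[family.genotypes[i]],
                    f"{family.called_probability(i):.4f}",
                ]
        self._fh.write("\t".join(fields) + "\n")

    def close(self) -> None:
        self._fh.close()


def open_writer(first_record: VariantRecord, path: str | Path):
    if first_record.source_format == "vcf":
        return VcfWriter(path, first_record.source.header)
    return TableWriter(path, first_record.table_samples or ())


def write_output(
    sites: Iterable[tuple[VariantRecord, PosteriorCall | None, PosteriorCall | None]],
    path: str | Path,
    ped: Pedigree,
) -> int:
    """Write annotated records; returns the number of records written.

    Non-candidate records are copied through unchanged (with missing
    result fields); every input record appears exactly once, in order.
    """
    writer = None
    count = 0
    try:
        for record, individual, family in sites:
            if writer is None:
                writer = open_writer(record, path)
            writer.write_site(record, ped, individual, family)
            count += 1
    finally:
        if writer is not None:
            writer.close()
    if writer is None:
        raise VariantIOError("no records to write")
    return count
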