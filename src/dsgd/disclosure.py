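"""Access-rights-based disclosure control for VCF output.

Genotype records carry enough information to re-identify an individual, so
the data owner releases only the subset of a VCF that a user's access
rights cover.  An :class:`AccessPolicy` selects records by one of five
modes — nothing, the first *N* records, genomic regions, an explicit
variant-ID list, or everything — and can additionally mask INFO / FORMAT
fields down to an allow-list.

Filtering operates on the VCF text stream, which makes it behave
identically on plain and gzip-compressed input and lets header lines pass
through byte-identically (plus exactly one provenance line).  Records are
never split, re-ordered or normalised: the filter is record-granular.
Coordinates are 1-based inclusive, the standard VCF convention.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import IO, Dict, Iterable, Iterator, List, Sequence, Tuple

from .errors import PolicyError, VcfParseError
from .io_utils import open_maybe_gzip

__all__ = [
    "AccessPolicy",
    "DisclosureResult",
    "normalize_policy",
    "filter_vcf",
    "count_matching",
    "PROVENANCE_KEY",
]

logger = logging.getLogger(__name__)

MODES = ("none", "count", "regions", "id_list", "all")
PROVENANCE_KEY = "##dsgd_filter"


@dataclass(frozen=True)
class AccessPolicy:
    """What subset of a VCF a user may receive.

    ``regions`` are (chromosome, start, end), 1-based inclusive, sorted and
    non-overlapping after :func:`normalize_policy`.  ``allowed_info_fields``
    and ``allowed_format_fields`` are either the string ``"all"`` or a
    frozenset of field names to retain.
    """

    user_id: str = "anonymous"
    mode: str = "none"
    max_records: int = 0
    regions: Tuple[Tuple[str, int, int], ...] = ()
    variant_ids: frozenset = frozenset()
    allowed_info_fields: object = "all"
    allowed_format_fields: object = "all"

    def provenance_line(self) -> str:
        return f"{PROVENANCE_KEY}=user={self.user_id};mode={self.mode}"


@dataclass
class DisclosureResult:
    """What was actually released for one filtering run."""

    records_in: int = 0
    records_out: int = 0
    fields_masked: int = 0
    output: str | None = None


def _parse_region(raw) -> Tuple[str, int, int]:
    if isinstance(raw, str):
        try:
            chrom, span = raw.split(":")
            start_s, end_s = span.replace(",", "").split("-")
            chrom, start, end = chrom, int(start_s), int(end_s)
        except ValueError:
            raise PolicyError(f"cannot parse region {raw!r}; expected 'chr:start-end'")
    else:
        try:
            chrom, start, end = raw[0], int(raw[1]), int(raw[2])
        except (TypeError, ValueError, IndexError):
            raise PolicyError(f"cannot parse region {raw!r}")
    if start < 1 or end < 1:
        raise PolicyError(f"region {raw!r}: coordinates are 1-based and positive")
    if start > end:
        raise PolicyError(f"region {raw!r}: start exceeds end")
    return str(chrom), start, end


def _merge_regions(
    regions: Iterable[Tuple[str, int, int]]
) -> Tuple[Tuple[str, int, int], ...]:
    """Sort regions and merge overlapping or touching spans per chromosome."""
    merged: List[Tuple[str, int, int]] = []
    for chrom, start, end in sorted(regions):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2] + 1:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end)))
        else:
            merged.append((chrom, start, end))
    return tuple(merged)


def normalize_policy(raw: dict | AccessPolicy | None) -> AccessPolicy:
    """Validate a raw policy mapping into a canonical :class:`AccessPolicy`.

    An empty or missing configuration yields the safe default: release
    nothing (mode ``none``).
    """
    if isinstance(raw, AccessPolicy):
        return AccessPolicy(
            user_id=raw.user_id,
            mode=raw.mode,
            max_records=raw.max_records,
            regions=_merge_regions(raw.regions),
            variant_ids=frozenset(raw.variant_ids),
            allowed_info_fields=_normalize_fields(raw.allowed_info_fields),
            allowed_format_fields=_normalize_fields(raw.allowed_format_fields),
        )
    raw = dict(raw or {})
    mode = raw.get("mode", "none")
    if mode not in MODES:
        raise PolicyError(f"unknown policy mode {mode!r}; expected one of {MODES}")
    max_records = int(raw.get("max_records", 0))
    if max_records < 0:
        raise PolicyError("max_records must be non-negative")
    regions = _merge_regions(_parse_region(r) for r in raw.get("regions", []))
    if mode == "regions" and not regions:
        logger.warning("regions mode with an empty region list releases nothing")
    return AccessPolicy(
        user_id=str(raw.get("user_id", "anonymous")),
        mode=mode,
        max_records=max_records,
        regions=regions,
        variant_ids=frozenset(str(v) for v in raw.get("variant_ids", [])),
        allowed_info_fields=_normalize_fields(raw.get("info_fields", raw.get("allowed_info_fields", "all"))),
        allowed_format_fields=_normalize_fields(raw.get("format_fields", raw.get("allowed_format_fields", "all"))),
    )


def _normalize_fields(value) -> object:
    if value == "all" or value is None:
        return "all"
    return frozenset(str(v) for v in value)


class _RegionIndex:
    """Sorted per-chromosome interval lookup over merged regions."""

    def __init__(self, regions: Sequence[Tuple[str, int, int]]):
        self._by_chrom: Dict[str, Tuple[List[int], List[int]]] = {}
        for chrom, start, end in regions:
            starts, ends = self._by_chrom.setdefault(chrom, ([], []))
            starts.append(start)
            ends.append(end)

    def __contains__(self, locus: Tuple[str, int]) -> bool:
        chrom, pos = locus
        if chrom not in self._by_chrom:
            return False
        starts, ends = self._by_chrom[chrom]
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos <= ends[i]


def _mask_fields(
    fields: List[str], policy: AccessPolicy
) -> Tuple[List[str], int]:
    """Apply INFO/FORMAT allow-lists to one record's columns."""
    masked = 0
    if policy.allowed_info_fields != "all" and len(fields) > 7:
        entries = fields[7].split(";") if fields[7] != "." else []
        kept = []
        for entry in entries:
            key = entry.split("=", 1)[0]
            if key in policy.allowed_info_fields:
                kept.append(entry)
            else:
                masked += 1
        fields[7] = ";".join(kept) if kept else "."
    if policy.allowed_format_fields != "all" and len(fields) > 8:
        keys = fields[8].split(":")
        keep_idx = [i for i, k in enumerate(keys) if k in policy.allowed_format_fields]
        masked += len(keys) - len(keep_idx)
        if keep_idx:
            fields[8] = ":".join(keys[i] for i in keep_idx)
            for col in range(9, len(fields)):
                vals = fields[col].split(":")
                fields[col] = ":".join(
                    vals[i] if i < len(vals) else "." for i in keep_idx
                )
        else:
            # nothing left to report per sample: release the site columns only
            del fields[8:]
    return fields, masked


def _filter_records(
    lines: Iterable[str], policy: AccessPolicy, result: DisclosureResult
) -> Iterator[str]:
    """Yield output lines (header + passing records), updating ``result``."""
    region_index = _RegionIndex(policy.regions)
    provenance = policy.provenance_line()
    in_header = True
    header_has_provenance = False
    for line_no, line in enumerate(lines, start=1):
        stripped = line.rstrip("\n")
        if not stripped and in_header:
            continue
        if stripped.startswith("##"):
            if stripped == provenance:
                header_has_provenance = True
            yield stripped
            continue
        if stripped.startswith("#"):
            if not header_has_provenance:
                yield provenance
            yield stripped
            in_header = False
            continue
        in_header = False
        result.records_in += 1
        fields = stripped.split("\t")
        if len(fields) < 8:
            raise VcfParseError(
                f"record with {len(fields)} columns (expected >= 8)", line_no
            )
        try:
            pos = int(fields[1])
        except ValueError:
            raise VcfParseError(f"non-integer POS {fields[1]!r}", line_no)

        if policy.mode == "none":
            take = False
        elif policy.mode == "all":
            take = True
        elif policy.mode == "count":
            take = result.records_out < policy.max_records
        elif policy.mode == "regions":
            take = (fields[0], pos) in region_index
        elif policy.mode == "id_list":
            ids = fields[2].split(";") if fields[2] != "." else []
            take = any(i in policy.variant_ids for i in ids)
        else:  # pragma: no cover - normalize_policy rejects unknown modes
            raise PolicyError(f"unknown mode {policy.mode!r}")
        if not take:
            continue
        fields, masked = _mask_fields(fields, policy)
        result.fields_masked += masked
        result.records_out += 1
        yield "\t".join(fields)


def filter_vcf(
    vcf_in: str | IO,
    policy: AccessPolicy | dict,
    out: str | IO | None,
) -> DisclosureResult:
    """Filter a VCF stream under an access policy.

    ``vcf_in`` and ``out`` may be paths (gzip detected / applied
    automatically) or open text streams; ``out=None`` counts without
    writing.  Header lines pass through verbatim plus one provenance line
    before ``#CHROM`` (never duplicated, so filtering is idempotent).
    """
    policy = normalize_policy(policy) if not isinstance(policy, AccessPolicy) else policy
    result = DisclosureResult(output=out if isinstance(out, str) else None)

    def run(in_stream, out_stream):
        for line in _filter_records(in_stream, policy, result):
            if out_stream is not None:
                out_stream.write(line + "\n")

    in_stream = open_maybe_gzip(vcf_in, "rt") if isinstance(vcf_in, str) else vcf_in
    try:
        if out is None or not isinstance(out, str):
            run(in_stream, out)
        else:
            with open_maybe_gzip(out, "wt") as out_stream:
                run(in_stream, out_stream)
    finally:
        if isinstance(vcf_in, str):
            in_stream.close()
    return result


def count_matching(vcf_in: str | IO, policy: AccessPolicy | dict) -> int:
    """Dry-run of :func:`filter_vcf`: how many records the policy releases."""
    return filter_vcf(vcf_in, policy, out=None).records_out
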