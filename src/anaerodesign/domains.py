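"""Protein-domain annotation parsing and domain-architecture matrices.

A *domain architecture* is the ordered list of domain accessions along a
protein (N- to C-terminal), used here as an orthology proxy across genomes:
two proteins with the same ordered accession list are treated as orthologs.
Within one genome, identical architectures are counted (copy number), and the
pair (architecture, copy number) serves as the orthology key where copy-number
identity matters; presence/absence views collapse copies.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import LabelError, ParseError

#: Separator joining domain accessions into an architecture key string.
KEY_SEPARATOR = ";"
#: Separator between an architecture string and its copy number in
#: copy-number-aware orthology keys, e.g. ``"PF00001;PF00002|c2"``.
COPY_SEPARATOR = "|c"

ANNOTATION_COLUMNS = ("strain_id", "protein_id", "domain_accession", "start", "end")


@dataclass(frozen=True)
class DomainHit:
    """One domain match on one protein (1-based, inclusive coordinates)."""

    strain_id: str
    protein_id: str
    domain_accession: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"invalid coordinates for {self.protein_id}/{self.domain_accession}: "
                f"start={self.start}, end={self.end} (need 1 <= start <= end)"
            )


def parse_domain_annotations(source: str | IO[str]) -> list[DomainHit]:
    """Parse a tab-separated domain annotation table into :class:`DomainHit` rows.

    The table has a header line with columns
    ``strain_id  protein_id  domain_accession  start  end``.
    Row order is preserved. Errors report 1-based line numbers (header = line 0).
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    header = source.readline()
    if not header:
        return []
    cols = header.rstrip("\n").split("\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in cols]
    if missing:
        raise ParseError(f"annotation header missing column(s): {', '.join(missing)}")
    idx = {c: cols.index(c) for c in ANNOTATION_COLUMNS}
    hits: list[DomainHit] = []
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < len(cols):
            raise ParseError(f"line {lineno}: expected {len(cols)} columns, got {len(fields)}")
        try:
            start = int(fields[idx["start"]])
            end = int(fields[idx["end"]])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinate ({exc})") from None
        try:
            hits.append(
                DomainHit(
                    strain_id=fields[idx["strain_id"]],
                    protein_id=fields[idx["protein_id"]],
                    domain_accession=fields[idx["domain_accession"]],
                    start=start,
                    end=end,
                )
            )
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return hits


def write_domain_annotations(hits: Iterable[DomainHit]) -> str:
    """Serialize hits back to the tab-separated annotation format."""
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for h in hits:
        lines.append(f"{h.strain_id}\t{h.protein_id}\t{h.domain_accession}\t{h.start}\t{h.end}")
    return "\n".join(lines) + "\n"


def build_architectures(hits: Iterable[DomainHit]) -> dict[str, dict[str, str]]:
    """Assemble per-protein architecture keys.

    Returns ``{strain_id: {protein_id: architecture_key}}`` where the key is
    the start-ordered accession list joined by :data:`KEY_SEPARATOR`.
    Ties on start are broken by end, then accession, so the result is
    independent of input row order. Proteins without hits contribute nothing.
    """
    per_protein: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        per_protein.setdefault((h.strain_id, h.protein_id), []).append(h)
    out: dict[str, dict[str, str]] = {}
    for (strain, protein), phits in per_protein.items():
        ordered = sorted(phits, key=lambda h: (h.start, h.end, h.domain_accession))
        key = KEY_SEPARATOR.join(h.domain_accession for h in ordered)
        out.setdefault(strain, {})[protein] = key
    return out


def strain_catalogs(protein_keys: Mapping[str, Mapping[str, str]]) -> dict[str, Counter]:
    """Collapse per-protein keys into per-strain copy counts.

    The copy number of an architecture in a strain is the number of proteins
    in that strain carrying it.
    """
    return {
        strain: Counter(proteins.values()) for strain, proteins in protein_keys.items()
    }


@dataclass
class ArchitectureMatrix:
    """Strains x architecture keys, integer copy counts.

    ``counts`` is a DataFrame indexed by strain, columns sorted
    lexicographically by architecture key.
    """

    counts: pd.DataFrame

    @property
    def strains(self) -> list[str]:
        return list(self.counts.index)

    @property
    def architectures(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def binary(self) -> pd.DataFrame:
        """Presence/absence view (copy number collapsed)."""
        return (self.counts > 0).astype(np.int8)

    def copy_number_view(self) -> pd.DataFrame:
        """Binary matrix over copy-number-aware orthology keys.

        Column ``arch|cN`` marks strains carrying exactly N copies of ``arch``,
        so an architecture present in two copies is a *different* ortholog from
        the single-copy form.
        """
        cols = {}
        for arch in self.counts.columns:
            col = self.counts[arch]
            for n in sorted(set(col[col > 0])):
                cols[f"{arch}{COPY_SEPARATOR}{n}"] = (col == n).astype(np.int8)
        return pd.DataFrame(cols, index=self.counts.index)


def build_matrix(
    catalogs: Mapping[str, Mapping[str, int]], labels: pd.DataFrame
) -> ArchitectureMatrix:
    """Assemble the strains x architectures copy-count matrix.

    ``labels`` is the strain table (columns ``strain_id``, ``lifestyle``) and
    fixes the row set and order: every catalog strain must be labelled, and
    labelled strains without annotations get all-zero rows.
    """
    label_strains = list(labels["strain_id"])
    label_set = set(label_strains)
    for strain in catalogs:
        if strain not in label_set:
            raise LabelError(f"strain {strain!r} in annotations but not in label table")
    all_keys = sorted({k for cat in catalogs.values() for k in cat})
    mat = np.zeros((len(label_strains), len(all_keys)), dtype=np.int64)
    key_idx = {k: j for j, k in enumerate(all_keys)}
    for i, strain in enumerate(label_strains):
        for key, count in catalogs.get(strain, {}).items():
            mat[i, key_idx[key]] = count
    return ArchitectureMatrix(
        counts=pd.DataFrame(mat, index=pd.Index(label_strains, name="strain_id"), columns=all_keys)
    )


def matrix_from_hits(hits: Iterable[DomainHit], labels: pd.DataFrame) -> ArchitectureMatrix:
    """Convenience: annotation hits -> architecture matrix in one step."""
    return build_matrix(strain_catalogs(build_architectures(hits)), labels)
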