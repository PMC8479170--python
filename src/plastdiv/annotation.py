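"""Feature annotation for the reference plastome, read from / written to GFF3.

GFF3 files use 1-based inclusive coordinates; internally every interval is
0-based half-open on the ungapped reference.  A :class:`Feature` is one
feature kind of one gene (its CDS, its exons, ...) with one or more parts in
*genomic* order plus an explicit transcription order, which lets trans-spliced
genes keep their biological part order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import FrameError, OutOfRangeError

GENE_SPAN_KINDS = ("gene", "tRNA", "rRNA")
FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA", "intron", "exon")


@dataclass
class Feature:
    """One feature kind of one gene.

    parts are (start, end) 0-based half-open intervals in genomic order;
    ``order`` gives the index of each part in transcription order (defaults
    to genomic order on '+', reverse genomic order on '-').
    """

    gene: str
    kind: str
    strand: str
    parts: list[tuple[int, int]]
    phases: list[int] | None = None
    order: list[int] | None = None
    product: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.parts), max(e for _, e in self.parts))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def transcription_parts(self) -> list[tuple[int, int]]:
        """Parts in transcription order (minus-strand parts still given as
        genomic intervals; callers reverse-complement each part)."""
        if self.order is not None:
            ranked = sorted(zip(self.order, self.parts))
            return [p for _, p in ranked]
        if self.strand == "-":
            return list(reversed(self.parts))
        return list(self.parts)


@dataclass
class AnnotationSet:
    """All features of the reference genome, validated against its length."""

    features: list[Feature]
    genome_length: int
    _by_gene: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for f in self.features:
            for s, e in f.parts:
                if s < 0 or e > self.genome_length or e < s:
                    raise OutOfRangeError(
                        f"{f.gene}/{f.kind} interval [{s},{e}) outside "
                        f"[0,{self.genome_length})"
                    )
        for gene in {f.gene for f in self.features if f.kind == "CDS"}:
            cds = self.feature(gene, "CDS")
            if cds.length % 3 != 0:
                raise FrameError(
                    f"CDS of {gene} has length {cds.length}, not divisible by 3"
                )

    def feature(self, gene: str, kind: str) -> Feature:
        key = (gene, kind)
        if key not in self._by_gene:
            for f in self.features:
                self._by_gene.setdefault((f.gene, f.kind), f)
        if key not in self._by_gene:
            raise KeyError(f"no {kind} feature for gene {gene!r}")
        return self._by_gene[key]

    def has_feature(self, gene: str, kind: str) -> bool:
        try:
            self.feature(gene, kind)
            return True
        except KeyError:
            return False

    def gene_spans(self) -> list[Feature]:
        """Features that define a gene's extent (gene/tRNA/rRNA span rows)."""
        return [f for f in self.features if f.kind in GENE_SPAN_KINDS]

    def cds_features(self) -> list[Feature]:
        """CDS features in annotation order (one per protein-coding gene)."""
        return [f for f in self.features if f.kind == "CDS"]

    def exon_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind in ("exon", "CDS")]

    def gene_names(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            if f.gene not in seen:
                seen.append(f.gene)
        return seen


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path: str | Path, genome_length: int) -> AnnotationSet:
    """Read a GFF3 annotation (1-based inclusive) into an AnnotationSet.

    Parts of multi-part features (multi-exon CDS, trans-spliced genes) are
    grouped by (gene, type); an optional ``part_order`` attribute records
    transcription order for trans-spliced cases.
    """
    grouped: dict[tuple[str, str], dict] = {}
    keys_in_order: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                continue
            _, _, ftype, start, end, _, strand, phase, attrs_text = cols
            if ftype not in FEATURE_KINDS:
                continue
            attrs = _parse_attributes(attrs_text)
            gene = attrs.get("gene") or attrs.get("Name") or attrs.get("ID")
            if gene is None:
                continue
            key = (gene, ftype)
            if key not in grouped:
                grouped[key] = {
                    "strand": strand,
                    "parts": [],
                    "phases": [],
                    "order": [],
                    "product": attrs.get("product"),
                    "has_order": False,
                }
                keys_in_order.append(key)
            rec = grouped[key]
            rec["parts"].append((int(start) - 1, int(end)))
            rec["phases"].append(int(phase) if phase not in (".", "") else 0)
            if "part_order" in attrs:
                rec["has_order"] = True
                rec["order"].append(int(attrs["part_order"]))
            else:
                rec["order"].append(len(rec["order"]))
    features = []
    for gene, ftype in keys_in_order:
        rec = grouped[(gene, ftype)]
        # keep parts in genomic order but preserve transcription order ranks
        ranked = sorted(
            zip(rec["parts"], rec["phases"], rec["order"]), key=lambda x: x[0]
        )
        features.append(
            Feature(
                gene=gene,
                kind=ftype,
                strand=rec["strand"],
                parts=[p for p, _, _ in ranked],
                phases=[ph for _, ph, _ in ranked] if ftype == "CDS" else None,
                order=[o for _, _, o in ranked] if rec["has_order"] else None,
                product=rec["product"],
            )
        )
    return AnnotationSet(features, genome_length)


def write_annotation(ann: AnnotationSet, path: str | Path, seqid: str = "reference") -> None:
    """Write the annotation as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ann.features:
            if f.order is not None:
                order = f.order
            else:
                tparts = f.transcription_parts()
                order = [tparts.index(p) for p in f.parts]
            phases = f.phases if f.phases is not None else ["."] * len(f.parts)
            for (s, e), ph, rank in zip(f.parts, phases, order):
                attrs = [f"ID={f.gene}.{f.kind}.{rank}", f"gene={f.gene}"]
                if f.product:
                    attrs.append(f"product={f.product}")
                if len(f.parts) > 1:
                    attrs.append(f"part_order={rank}")
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            "plastdiv",
                            f.kind,
                            str(s + 1),
                            str(e),
                            ".",
                            f.strand,
                            str(ph),
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
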