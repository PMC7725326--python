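"""BioPAX Level 3 input/output.

Pathway composition is read from BioPAX L3 OWL/XML: the ``bp:Pathway``
element supplies the pathway identity and each ``bp:ProteinReference``
one member enzyme (with its embedded sequence when present; otherwise a
user-supplied local FASTA can resolve it — never the network).

Reconstruction states are written back as a structured custom comment,
since BioPAX L3 has no native presence/absence attribute.  The flag is a
``bp:comment`` sub-element whose text is exactly

    $$custom comment$$:present   or   $$custom comment$$:absent

(no whitespace), attached to the Pathway and/or ProteinReference
elements.  Annotation replaces any previous flag, so repeated passes
leave exactly one flag per element, and stripping the flags restores a
document canonically equal to the input.
"""

from __future__ import annotations

import re
import warnings
from typing import Mapping

from lxml import etree

from .errors import FormatError, MissingDataError, ParameterError
from .profiles import PathwayDefinition

BP_NS = "http://www.biopax.org/release/biopax-level3.owl#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
XSD_STRING = "http://www.w3.org/2001/XMLSchema#string"
OWL_NS = "http://www.w3.org/2002/07/owl#"

FLAG_PREFIX = "$$custom comment$$:"
FLAG_PATTERN = re.compile(r"^\$\$custom comment\$\$:(present|absent)$")

_NSMAP = {"bp": BP_NS, "rdf": RDF_NS, "owl": OWL_NS}


def load(source) -> etree._ElementTree:
    """Parse a BioPAX L3 OWL/XML document from a path or file object."""
    try:
        return etree.parse(source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise FormatError(f"cannot parse BioPAX document: {exc}") from exc


def write(doc: etree._ElementTree, path) -> None:
    doc.write(str(path), xml_declaration=True, encoding="UTF-8")


def canonical_bytes(doc: etree._ElementTree) -> bytes:
    """Canonical (C14N) serialization, for content-equality comparisons."""
    return etree.tostring(doc, method="c14n2")


def _element_id(elem) -> str:
    return (
        elem.get(f"{{{RDF_NS}}}about")
        or elem.get(f"{{{RDF_NS}}}ID")
        or ""
    )


def _find_all(doc, tag: str):
    return doc.findall(f".//{{{BP_NS}}}{tag}")


def extract_proteins(doc) -> tuple[PathwayDefinition, dict[str, str | None]]:
    """Pathway identity plus member proteins (and embedded sequences).

    Returns the definition built from the first ``bp:Pathway`` element
    and all ``bp:ProteinReference`` elements in document order, and a map
    enzyme id -> sequence string or ``None`` when no sequence is embedded.
    A document without a Pathway element is an error; one without protein
    references yields an empty definition with a warning (it cannot be
    profiled downstream).
    """
    if isinstance(doc, (str, bytes)) or hasattr(doc, "read"):
        doc = load(doc)
    pathways = _find_all(doc, "Pathway")
    if not pathways:
        raise MissingDataError("document contains no bp:Pathway element")
    pathway_elem = pathways[0]
    pathway_id = _element_id(pathway_elem)
    name_elem = pathway_elem.find(f"{{{BP_NS}}}displayName")
    if name_elem is None:
        name_elem = pathway_elem.find(f"{{{BP_NS}}}name")
    name = name_elem.text if name_elem is not None and name_elem.text else pathway_id

    enzyme_ids: list[str] = []
    sequences: dict[str, str | None] = {}
    for pref in _find_all(doc, "ProteinReference"):
        pid = _element_id(pref)
        if not pid:
            raise FormatError("ProteinReference without rdf:about/rdf:ID")
        enzyme_ids.append(pid)
        seq_elem = pref.find(f"{{{BP_NS}}}sequence")
        sequences[pid] = (
            seq_elem.text if seq_elem is not None and seq_elem.text else None
        )
    if not enzyme_ids:
        warnings.warn(
            f"pathway {pathway_id!r} has no ProteinReference elements; "
            "it cannot be profiled",
            stacklevel=2,
        )
    return (
        PathwayDefinition(pathway_id=pathway_id, enzyme_ids=enzyme_ids, name=name),
        sequences,
    )


def resolve_sequences(
    sequences: dict[str, str | None], fasta_path
) -> dict[str, str | None]:
    """Fill missing sequences from a local FASTA file, matching by id."""
    from Bio import SeqIO

    local = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    return {
        pid: (seq if seq is not None else local.get(pid))
        for pid, seq in sequences.items()
    }


def _is_flag_comment(elem) -> bool:
    return (
        elem.tag == f"{{{BP_NS}}}comment"
        and elem.text is not None
        and elem.text.startswith(FLAG_PREFIX)
    )


def _set_flag(elem, state: str) -> None:
    if state not in ("present", "absent"):
        raise ParameterError(f"state must be 'present' or 'absent', got {state!r}")
    for old in [c for c in elem if _is_flag_comment(c)]:
        elem.remove(old)
    comment = etree.SubElement(elem, f"{{{BP_NS}}}comment")
    comment.set(f"{{{RDF_NS}}}datatype", XSD_STRING)
    comment.text = FLAG_PREFIX + state


def annotate_states(
    doc: etree._ElementTree,
    pathway_state: str | None = None,
    protein_states: Mapping[str, str] | None = None,
) -> etree._ElementTree:
    """Set presence/absence flags on the Pathway and named proteins.

    Replaces any existing flag, so the operation is idempotent: after any
    number of passes each annotated element carries exactly one flag.
    """
    if pathway_state is not None:
        pathways = _find_all(doc, "Pathway")
        if not pathways:
            raise MissingDataError("document contains no bp:Pathway element")
        _set_flag(pathways[0], pathway_state)
    if protein_states:
        by_id = {_element_id(p): p for p in _find_all(doc, "ProteinReference")}
        unknown = sorted(set(protein_states) - set(by_id))
        if unknown:
            raise MissingDataError(f"unknown protein ids: {unknown}")
        for pid, state in protein_states.items():
            _set_flag(by_id[pid], state)
    return doc


def strip_annotations(doc: etree._ElementTree) -> etree._ElementTree:
    """Remove every presence/absence flag comment from the document."""
    # materialize first: removing nodes while iterating skips siblings
    for elem in list(doc.iter()):
        for child in [c for c in elem if _is_flag_comment(c)]:
            elem.remove(child)
    return doc


def iter_flags(doc: etree._ElementTree):
    """Yield (element id, flag text) for every flag comment in the document."""
    for elem in doc.iter():
        if not isinstance(elem.tag, str):
            continue
        for child in elem:
            if _is_flag_comment(child):
                yield _element_id(elem), child.text


def make_document(
    pathway_id: str,
    name: str,
    protein_ids: list[str],
    sequences: Mapping[str, str] | None = None,
) -> etree._ElementTree:
    """Build a minimal synthetic BioPAX L3 document (tests and simulations)."""
    nsmap = {"bp": BP_NS, "rdf": RDF_NS, "owl": OWL_NS}
    root = etree.Element(f"{{{RDF_NS}}}RDF", nsmap=nsmap)
    pathway = etree.SubElement(root, f"{{{BP_NS}}}Pathway")
    pathway.set(f"{{{RDF_NS}}}about", pathway_id)
    disp = etree.SubElement(pathway, f"{{{BP_NS}}}displayName")
    disp.set(f"{{{RDF_NS}}}datatype", XSD_STRING)
    disp.text = name
    for pid in protein_ids:
        pref = etree.SubElement(root, f"{{{BP_NS}}}ProteinReference")
        pref.set(f"{{{RDF_NS}}}about", pid)
        if sequences and sequences.get(pid):
            seq = etree.SubElement(pref, f"{{{BP_NS}}}sequence")
            seq.set(f"{{{RDF_NS}}}datatype", XSD_STRING)
            seq.text = sequences[pid]
    return etree.ElementTree(root)
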