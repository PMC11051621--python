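"""SemEval-2013 Task 9 corpus handling.

Parses the DDI-extraction XML dialect (documents → sentences → entities with
character offsets → labelled pairs), generates anonymised candidate drug-pair
instances (the two target mentions replaced by ``DRUG1``/``DRUG2``), applies
the standard negative-instance filtering rules, and maps drug surface names to
DrugBank identifiers.

Character offsets in the corpus are 0-based *inclusive* ranges ("12-20" covers
nine characters); internally every span is half-open ``(start, stop)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

#: fixed label order used everywhere (stable class indices across artifacts)
CLASSES = ("Negative", "Mechanism", "Effect", "Advise", "Int")
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

# ddi type attribute values in the corpus → canonical labels
_TYPE_ALIASES = {
    "mechanism": "Mechanism", "effect": "Effect", "advise": "Advise",
    "advice": "Advise", "int": "Int", "negative": "Negative",
}


@dataclass
class Entity:
    id: str
    text: str
    span: tuple[int, int]          # half-open, in sentence text
    drug_type: str = "drug"


@dataclass
class AnnotatedSentence:
    doc_id: str
    sent_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    pairs: list[tuple[str, str, str]] = field(default_factory=list)  # (e1, e2, label)


@dataclass
class CandidateInstance:
    """One unordered drug pair from a sentence, mentions anonymised in order."""

    sent_id: str
    text: str                       # anonymised sentence
    d1_span: tuple[int, int]        # DRUG1 token span in anonymised text
    d2_span: tuple[int, int]
    name1: str                      # original surface forms (appearance order)
    name2: str
    label: str
    orig_text: str = ""
    orig_span1: tuple[int, int] = (0, 0)
    orig_span2: tuple[int, int] = (0, 0)
    other_entity_spans: list[tuple[int, int]] = field(default_factory=list)
    drugbank_id1: str | None = None
    drugbank_id2: str | None = None


def _parse_char_offset(raw: str, sent_id: str, ent_id: str) -> tuple[int, int]:
    """'12-20' (inclusive) → (12, 21); discontinuous offsets keep the first span."""
    parts = raw.split(";")
    if len(parts) > 1:
        logger.warning("entity %s in %s has discontinuous offset %r; keeping "
                       "the first span", ent_id, sent_id, raw)
    m = re.fullmatch(r"\s*(\d+)-(\d+)\s*", parts[0])
    if not m:
        raise ValueError(f"unparseable charOffset {raw!r} for entity {ent_id} "
                         f"in sentence {sent_id}")
    start, last = int(m.group(1)), int(m.group(2))
    return start, last + 1


def parse_semeval(source) -> list[AnnotatedSentence]:
    """Parse one SemEval DDI XML document (path, file object, or XML string)."""
    if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("<"):
        tree = etree.parse(str(source))
    elif isinstance(source, str):
        tree = etree.ElementTree(etree.fromstring(source.encode()))
    else:
        tree = etree.parse(source)
    root = tree.getroot()
    docs = [root] if root.tag == "document" else root.findall(".//document")
    sentences: list[AnnotatedSentence] = []
    for doc in docs:
        for sent in doc.findall("sentence"):
            sid = sent.get("id", "")
            text = sent.get("text", "")
            ann = AnnotatedSentence(doc_id=doc.get("id", ""), sent_id=sid, text=text)
            for ent in sent.findall("entity"):
                span = _parse_char_offset(ent.get("charOffset", ""), sid,
                                          ent.get("id", "?"))
                if span[1] > len(text) or span[0] < 0:
                    raise ValueError(f"entity {ent.get('id')} offset {span} outside "
                                     f"sentence {sid} (length {len(text)})")
                ann.entities.append(Entity(id=ent.get("id", ""),
                                           text=ent.get("text", text[span[0]:span[1]]),
                                           span=span,
                                           drug_type=ent.get("type", "drug")))
            known = {e.id for e in ann.entities}
            for pair in sent.findall("pair"):
                e1, e2 = pair.get("e1", ""), pair.get("e2", "")
                for e in (e1, e2):
                    if e not in known:
                        raise ValueError(f"pair {pair.get('id')} in sentence {sid} "
                                         f"references unknown entity {e!r}")
                if pair.get("ddi", "false").lower() == "true":
                    raw = pair.get("type", "Int").lower()
                    label = _TYPE_ALIASES.get(raw, "Int")
                else:
                    label = "Negative"
                ann.pairs.append((e1, e2, label))
            sentences.append(ann)
    return sentences


def serialize_semeval(sentences: list[AnnotatedSentence]) -> str:
    """Re-emit sentences as SemEval XML (inclusive charOffsets), one corpus root."""
    root = etree.Element("corpus")
    by_doc: dict[str, etree._Element] = {}
    for ann in sentences:
        doc = by_doc.get(ann.doc_id)
        if doc is None:
            doc = etree.SubElement(root, "document", id=ann.doc_id)
            by_doc[ann.doc_id] = doc
        s = etree.SubElement(doc, "sentence", id=ann.sent_id, text=ann.text)
        for e in ann.entities:
            etree.SubElement(s, "entity", id=e.id, text=e.text, type=e.drug_type,
                             charOffset=f"{e.span[0]}-{e.span[1] - 1}")
        for i, (e1, e2, label) in enumerate(ann.pairs):
            attrs = {"id": f"{ann.sent_id}.p{i}", "e1": e1, "e2": e2}
            if label == "Negative":
                attrs["ddi"] = "false"
            else:
                attrs["ddi"] = "true"
                attrs["type"] = label.lower()
            etree.SubElement(s, "pair", **attrs)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _resolve_overlaps(entities: list[Entity]) -> list[Entity]:
    """Among overlapping mentions keep the longer one (for replacement)."""
    kept: list[Entity] = []
    for e in sorted(entities, key=lambda x: (x.span[1] - x.span[0]), reverse=True):
        if any(e.span[0] < k.span[1] and k.span[0] < e.span[1] for k in kept):
            logger.warning("entity %s (%r) overlaps a longer mention; skipped for "
                           "replacement", e.id, e.text)
            continue
        kept.append(e)
    return sorted(kept, key=lambda x: x.span)


def generate_candidates(sentence: AnnotatedSentence) -> list[CandidateInstance]:
    """All C(n,2) anonymised drug-pair instances of one sentence.

    Pairs are ordered by first-mention position; the earlier mention becomes
    DRUG1.  Labels come from the gold pairs (either orientation), defaulting
    to Negative.  Only the two target mentions are replaced.
    """
    usable = _resolve_overlaps(sentence.entities)
    gold = {}
    for e1, e2, label in sentence.pairs:
        gold[frozenset((e1, e2))] = label
    out: list[CandidateInstance] = []
    for a, b in combinations(usable, 2):
        first, second = sorted((a, b), key=lambda e: e.span)
        label = gold.get(frozenset((a.id, b.id)), "Negative")
        text = sentence.text
        # replace right-to-left so the first span's offsets stay valid
        text = text[:second.span[0]] + "DRUG2" + text[second.span[1]:]
        text = text[:first.span[0]] + "DRUG1" + text[first.span[1]:]
        d1_span = (first.span[0], first.span[0] + 5)
        shift = 5 - (first.span[1] - first.span[0])
        d2_span = (second.span[0] + shift, second.span[0] + shift + 5)
        others = [e.span for e in sentence.entities
                  if e.id not in (first.id, second.id)]
        out.append(CandidateInstance(
            sent_id=sentence.sent_id, text=text, d1_span=d1_span, d2_span=d2_span,
            name1=first.text, name2=second.text, label=label,
            orig_text=sentence.text, orig_span1=first.span,
            orig_span2=second.span, other_entity_spans=others))
    out.sort(key=lambda c: (c.orig_span1, c.orig_span2))
    return out


# ---------------------------------------------------------------------------
# negative-instance filtering (heuristic operationalisations, individually
# toggleable; gold positives are never removed)
# ---------------------------------------------------------------------------

def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


def _is_abbreviation(short: str, long: str) -> bool:
    """`short` reads as an acronym of `long` (initial letters of its words)."""
    s, words = short.strip(), re.findall(r"[A-Za-z]+", long)
    if not (2 <= len(s) <= 6) or not s.isalpha() or not s.isupper():
        return False
    initials = "".join(w[0] for w in words).upper()
    return len(words) >= 2 and initials == s.upper()


def rule1_same_name(inst: CandidateInstance) -> bool:
    """Both mentions refer to the same drug (identical name or acronym of it)."""
    n1, n2 = _normalize_name(inst.name1), _normalize_name(inst.name2)
    if n1 == n2:
        return True
    return _is_abbreviation(inst.name1, inst.name2) or \
        _is_abbreviation(inst.name2, inst.name1)


_COORD_FILLER = re.compile(
    r"""^(?:\s|,|;|and\b|or\b|e\.g\.,?)*$""", re.IGNORECASE)


def rule2_coordinate(inst: CandidateInstance) -> bool:
    """Both mentions sit in one coordinate list: everything between them is
    other drug mentions, commas/semicolons, conjunctions, or 'e.g.'."""
    lo, hi = inst.orig_span1[1], inst.orig_span2[0]
    if hi <= lo:
        return False
    between = inst.orig_text[lo:hi]
    # blank out intervening drug mentions before checking the filler pattern
    for s, e in inst.other_entity_spans:
        if s >= lo and e <= hi:
            between = between[:s - lo] + " " * (e - s) + between[e - lo:]
    return bool(_COORD_FILLER.match(between))


_PAREN_LINK = re.compile(r"^\s*\(\s*$")
_APPOSITION = re.compile(r"^\s*,?\s*(?:such\s+as|including)\s+$", re.IGNORECASE)


def rule3_special_case(inst: CandidateInstance) -> bool:
    """One mention is a special case of the other: parenthesised immediately
    after it, or linked by 'such as' / 'including'."""
    lo, hi = inst.orig_span1[1], inst.orig_span2[0]
    if hi < lo:
        return False
    between = inst.orig_text[lo:hi]
    after = inst.orig_text[inst.orig_span2[1]:inst.orig_span2[1] + 2]
    if _PAREN_LINK.match(between) and after.strip().startswith(")"):
        return True
    return bool(_APPOSITION.match(between))


_RULES = {"rule1": rule1_same_name, "rule2": rule2_coordinate,
          "rule3": rule3_special_case}


def filter_negatives(instances: list[CandidateInstance],
                     enabled: tuple[str, ...] = ("rule1", "rule2", "rule3"),
                     ) -> tuple[list[CandidateInstance], dict[str, int]]:
    """Drop Negative-labelled candidates matching any enabled rule.

    Returns the survivors and per-rule removal counts (an instance is counted
    once, under the first rule that fires).
    """
    survivors: list[CandidateInstance] = []
    removed = {name: 0 for name in enabled}
    for inst in instances:
        fired = None
        if inst.label == "Negative":
            for name in enabled:
                if _RULES[name](inst):
                    fired = name
                    break
        if fired is None:
            survivors.append(inst)
        else:
            removed[fired] += 1
            logger.debug("filtered (%s): %s / %s in %s", fired, inst.name1,
                         inst.name2, inst.sent_id)
    return survivors, removed


_CANDIDATE_COLUMNS = ("sent_id", "text", "d1_start", "d1_stop", "d2_start",
                      "d2_stop", "name1", "name2", "label", "drugbank_id1",
                      "drugbank_id2")


def write_candidates(instances: list[CandidateInstance], path) -> None:
    """Candidate-instance table as TSV; the text column is JSON-escaped."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CANDIDATE_COLUMNS) + "\n")
        for c in instances:
            row = (c.sent_id, json.dumps(c.text), c.d1_span[0], c.d1_span[1],
                   c.d2_span[0], c.d2_span[1], c.name1, c.name2, c.label,
                   c.drugbank_id1 or "", c.drugbank_id2 or "")
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_candidates(path) -> list[CandidateInstance]:
    import json

    import csv

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     quoting=csv.QUOTE_NONE)
    out = []
    for row in df.itertuples(index=False):
        out.append(CandidateInstance(
            sent_id=row.sent_id, text=json.loads(row.text),
            d1_span=(int(row.d1_start), int(row.d1_stop)),
            d2_span=(int(row.d2_start), int(row.d2_stop)),
            name1=row.name1, name2=row.name2, label=row.label,
            drugbank_id1=row.drugbank_id1 or None,
            drugbank_id2=row.drugbank_id2 or None))
    return out


def load_drug_mapping(path_or_records) -> dict[str, str]:
    """2-column TSV (drug name → DrugBank ID) as a normalised-name dict."""
    if isinstance(path_or_records, dict):
        items = list(path_or_records.items())
    else:
        df = pd.read_csv(path_or_records, sep="\t", header=None, comment="#",
                         dtype=str, keep_default_na=False)
        if df.shape[1] != 2:
            raise ValueError(f"mapping table must have 2 columns, got {df.shape[1]}")
        items = list(df.itertuples(index=False, name=None))
    mapping: dict[str, str] = {}
    for name, dbid in items:
        key = _normalize_name(str(name))
        if key in mapping and mapping[key] != dbid:
            raise ValueError(f"conflicting DrugBank IDs for {name!r}: "
                             f"{mapping[key]} vs {dbid}")
        mapping[key] = str(dbid)
    return mapping


def map_to_drugbank(instances: list[CandidateInstance], mapping,
                    ) -> tuple[list[CandidateInstance], int]:
    """Attach DrugBank IDs; drop (and count) instances with an unmapped drug."""
    if not isinstance(mapping, dict) or any(
            k != _normalize_name(k) for k in mapping):
        mapping = load_drug_mapping(mapping)
    kept: list[CandidateInstance] = []
    dropped = 0
    for inst in instances:
        id1 = mapping.get(_normalize_name(inst.name1))
        id2 = mapping.get(_normalize_name(inst.name2))
        if id1 is None or id2 is None:
            dropped += 1
            continue
        kept.append(replace(inst, drugbank_id1=id1, drugbank_id2=id2))
    if dropped:
        logger.info("dropped %d instances lacking a DrugBank ID", dropped)
    return kept, dropped
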