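"""Derive the prefix-closed concept hierarchy and stable node codes.

i2b2 organizes facts under a tree of backslash-delimited concept paths; the
engine derives that tree mechanically from the expanded ER model: one folder
per study and entity, one concept leaf per (declared or generated)
attribute, one modifier node per meta-attribute beneath its concept. Codes
are digest prefixes of the full path, so they are stable across runs and
machines without a database sequence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal

from .config import StagingConfig
from .cleanse import ColumnProfile
from .errors import ConfigSchemaError
from .report import AnomalyLog
from ._util import sanitize_segment

NodeKind = Literal["folder", "concept", "modifier"]
ValueType = Literal["numeric", "categorical", "date", "text", "none"]


@dataclass(frozen=True)
class OntologyNode:
    full_path: str
    name: str
    level: int
    kind: NodeKind
    value_type: ValueType = "none"
    code: str = ""

    def __post_init__(self) -> None:
        if not (self.full_path.startswith("\\") and self.full_path.endswith("\\")):
            raise ValueError(f"concept path must be \\-delimited: {self.full_path!r}")
        segments = self.full_path.strip("\\").split("\\")
        if self.level != len(segments):
            raise ValueError(f"level {self.level} inconsistent with path {self.full_path!r}")


@dataclass
class OntologyTree:
    root: OntologyNode
    nodes: list[OntologyNode] = field(default_factory=list)

    def paths(self) -> set[str]:
        return {n.full_path for n in self.nodes}

    def get(self, full_path: str) -> OntologyNode:
        for n in self.nodes:
            if n.full_path == full_path:
                return n
        raise KeyError(full_path)

    def concepts(self) -> list[OntologyNode]:
        return [n for n in self.nodes if n.kind == "concept"]

    def modifiers_of(self, concept_path: str) -> list[OntologyNode]:
        return [
            n
            for n in self.nodes
            if n.kind == "modifier" and n.full_path.startswith(concept_path)
        ]

    def is_prefix_closed(self) -> bool:
        paths = self.paths()
        for n in self.nodes:
            segments = n.full_path.strip("\\").split("\\")
            for k in range(1, len(segments)):
                if "\\" + "\\".join(segments[:k]) + "\\" not in paths:
                    return False
        return True


def concept_path(study_label: str, entity: str, attribute: str | None = None) -> str:
    """Canonical path ``\\study\\entity\\[attribute\\]`` with sanitized segments."""
    parts = [sanitize_segment(study_label), sanitize_segment(entity)]
    if attribute is not None:
        parts.append(sanitize_segment(attribute))
    return "\\" + "\\".join(parts) + "\\"


def build_ontology(
    cfg: StagingConfig,
    profiles: dict[tuple[str, str], ColumnProfile] | None = None,
) -> OntologyTree:
    """Build the concept tree for an (EAV-expanded) configuration.

    ``profiles`` maps (entity, attribute) to the attribute's value profile;
    absent profiles fall back to the declared type or text. Sibling order is
    lexicographic on the full path, making the tree deterministic. Two
    distinct attributes whose names sanitize to the same segment are a hard
    error rather than a silent merge.
    """
    profiles = profiles or {}
    study_seg = sanitize_segment(cfg.study_label)
    root = OntologyNode("\\" + study_seg + "\\", cfg.study_label, 1, "folder")
    nodes: dict[str, OntologyNode] = {root.full_path: root}
    origin: dict[str, str] = {}

    for entity in cfg.entities:
        epath = concept_path(cfg.study_label, entity.name)
        _claim(nodes, origin, epath, f"entity {entity.name!r}")
        nodes.setdefault(
            epath, OntologyNode(epath, entity.name, 2, "folder")
        )
        for attr in entity.attributes:
            apath = concept_path(cfg.study_label, entity.name, attr.name)
            _claim(nodes, origin, apath, f"attribute {entity.name}.{attr.name}")
            profile = profiles.get((entity.name, attr.name))
            if profile is not None:
                vtype: ValueType = profile.inferred_type
            elif attr.declared_type != "auto":
                vtype = attr.declared_type
            else:
                vtype = "text"
            nodes[apath] = OntologyNode(apath, attr.name, 3, "concept", vtype)
            for meta in attr.meta_attributes:
                mpath = apath + sanitize_segment(meta.name) + "\\"
                _claim(nodes, origin, mpath, f"meta {entity.name}.{attr.name}.{meta.name}")
                nodes[mpath] = OntologyNode(mpath, meta.name, 4, "modifier", "text")

    tree = OntologyTree(root=root, nodes=sorted(nodes.values(), key=lambda n: n.full_path))
    assert tree.is_prefix_closed()
    return tree


def _claim(nodes: dict, origin: dict[str, str], path: str, source: str) -> None:
    prior = origin.get(path)
    if prior is not None and prior != source:
        raise ConfigSchemaError(
            f"ontology path collision after sanitization: {path!r} claimed by both "
            f"{prior} and {source}"
        )
    origin[path] = source


def assign_codes(tree: OntologyTree, log: AnomalyLog | None = None) -> OntologyTree:
    """Assign injective, run-stable codes: digest prefixes of each full path.

    A node's code depends only on its own path, so adding unrelated nodes
    never changes existing codes. On the (astronomically unlikely) prefix
    collision the digest is lengthened until injective, with a log entry.
    """
    length = 16
    while True:
        codes = {
            n.full_path: hashlib.sha256(n.full_path.encode("utf-8")).hexdigest()[:length]
            for n in tree.nodes
        }
        if len(set(codes.values())) == len(codes):
            break
        length += 8
        if log is not None:
            log.add("ontology", "code-collision", f"digest collision; lengthening codes to {length}")
    new_nodes = [
        OntologyNode(n.full_path, n.name, n.level, n.kind, n.value_type, codes[n.full_path])
        for n in tree.nodes
    ]
    root = next(n for n in new_nodes if n.full_path == tree.root.full_path)
    return OntologyTree(root=root, nodes=new_nodes)
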