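"""Atom-feed syndication of terminology releases.

A terminology node can act both as a client (discover releases in a feed,
download and install them) and as a server (publish a feed over its own
store), which lets nodes chain: upstream publishes, midstream consumes and
republishes, downstream consumes.

Each feed entry describes one artefact of a code-system release: either a
prebuilt, checksummed **binary index** (this engine's private serialization
of an indexed record — preferred, because rebuilding an index from source
is the expensive step) or the **source files** (an RF2 snapshot archive, or
a normalized ontology-JSON bundle). Installation preference is strictly::

    compatible binary index  >  source files  >  failure

where "compatible" means the entry's index format version equals the
version this build writes.

Entry metadata rides in Atom ``category`` terms plus a small custom
namespace for content identity, version, index format and SHA-256
checksum.
"""
from __future__ import annotations

import datetime as _dt
import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from lxml import etree

from . import rf2 as _rf2
from .errors import (
    ContentUnavailable,
    FeedParseError,
    IncompatibleIndexError,
    IntegrityError,
)
from .model import CodeSystemRecord, TerminologyStore, transitive_closure, version_key

ATOM_NS = "http://www.w3.org/2005/Atom"
SYND_NS = "urn:termserve:syndication:1"
FORMAT_VERSION = "1"  # binary index schema version written by this build

CONTENT_KINDS = ("binary-index", "rf2-source", "owl-source")


@dataclass
class FeedEntry:
    entry_id: str
    title: str
    content_kind: str
    content_item_identifier: str
    content_item_version: str
    link: str
    checksum: str
    format_version: str = ""
    updated: str = ""
    usable: bool = True
    problems: list[str] = field(default_factory=list)

    def validate(self) -> list[str]:
        problems = []
        if self.content_kind not in CONTENT_KINDS:
            problems.append(f"unknown content kind {self.content_kind!r}")
        if len(self.checksum) != 64 or any(
            c not in "0123456789abcdef" for c in self.checksum.lower()
        ):
            problems.append("checksum is not 64 hex characters")
        if not self.link:
            problems.append("missing link")
        if not self.content_item_identifier:
            problems.append("missing content item identifier")
        return problems


# -- binary index -------------------------------------------------------------

def serialize_binary_index(record: CodeSystemRecord) -> bytes:
    """Checksum-stable serialization of a record plus its prebuilt tables.

    Canonical JSON (sorted keys, fixed separators) of the record, its
    transitive closure and its prefix-index word table, under a
    self-describing header.
    """
    from . import search as _search

    closure = sorted(transitive_closure(record, include_inactive=True))
    index = _search.build_prefix_index(record)
    payload = {
        "formatVersion": FORMAT_VERSION,
        "contentItemIdentifier": record.url,
        "contentItemVersion": record.version,
        "codeSystem": record.to_dict(),
        "closure": [list(p) for p in closure],
        "prefixIndex": {"entries": [list(e) for e in index.entries]},
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":")).encode("utf-8")


def deserialize_binary_index(payload: bytes) -> CodeSystemRecord:
    try:
        data = json.loads(payload.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise IncompatibleIndexError(f"not a binary index: {exc}")
    if data.get("formatVersion") != FORMAT_VERSION:
        raise IncompatibleIndexError(
            f"index format {data.get('formatVersion')!r}, "
            f"this build reads {FORMAT_VERSION!r}"
        )
    record = CodeSystemRecord.from_dict(data["codeSystem"])
    record._closure_cache["full"] = frozenset(
        (a, d) for a, d in data.get("closure", [])
    )
    return record


# -- source archives ----------------------------------------------------------

def serialize_rf2_source(record: CodeSystemRecord) -> bytes:
    """ZIP archive of an RF2 snapshot projected from the record."""
    bundle = _rf2.record_to_bundle(record)
    buf = io.BytesIO()
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        _rf2.write_rf2_snapshot(bundle, tmp)
        with zipfile.ZipFile(buf, "w", zipfile.ZIP_DEFLATED) as zf:
            for path in sorted(Path(tmp).iterdir()):
                zf.writestr(path.name, path.read_bytes())
    return buf.getvalue()


def install_rf2_source(payload: bytes, system_url: str, version: str) -> CodeSystemRecord:
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        with zipfile.ZipFile(io.BytesIO(payload)) as zf:
            zf.extractall(tmp)
        bundle = _rf2.read_rf2_snapshot(tmp)
        return _rf2.build_code_system(bundle, system_url, version)


def serialize_owl_source(main, imports: dict) -> bytes:
    """Ontology-JSON bundle: the main document plus embedded imports."""
    data = {
        "main": main.to_dict(),
        "imports": {iri: doc.to_dict() for iri, doc in imports.items()},
    }
    return json.dumps(data, sort_keys=True, separators=(",", ":")).encode("utf-8")


def install_owl_source(payload: bytes, config_id: str = "syndicated") -> CodeSystemRecord:
    from . import owl as _owl

    data = json.loads(payload.decode("utf-8"))
    main = _owl.OntologyDocument.from_dict(data["main"])
    imported = {
        iri: _owl.OntologyDocument.from_dict(doc)
        for iri, doc in data.get("imports", {}).items()
    }
    record, _ = _owl.to_code_system(
        main, imported.get, _owl.TransformConfig(id=config_id)
    )
    return record


# -- feed parsing / generation ------------------------------------------------

def parse_feed(atom_xml: bytes | str) -> list[FeedEntry]:
    """Parse an Atom feed; foreign/incomplete entries are kept, flagged unusable."""
    if isinstance(atom_xml, str):
        atom_xml = atom_xml.encode("utf-8")
    try:
        root = etree.fromstring(atom_xml)
    except etree.XMLSyntaxError as exc:
        raise FeedParseError(str(exc))

    entries = []
    for el in root.findall(f"{{{ATOM_NS}}}entry"):
        def text(tag, ns=ATOM_NS):
            node = el.find(f"{{{ns}}}{tag}")
            return node.text if node is not None and node.text else ""

        link_el = el.find(f"{{{ATOM_NS}}}link")
        kind = ""
        for cat in el.findall(f"{{{ATOM_NS}}}category"):
            if cat.get("scheme") == SYND_NS + "#content-kind":
                kind = cat.get("term", "")
        entry = FeedEntry(
            entry_id=text("id"),
            title=text("title"),
            content_kind=kind,
            content_item_identifier=text("contentItemIdentifier", SYND_NS),
            content_item_version=text("contentItemVersion", SYND_NS),
            format_version=text("formatVersion", SYND_NS),
            checksum=text("checksum", SYND_NS),
            link=link_el.get("href", "") if link_el is not None else "",
            updated=text("updated"),
        )
        entry.problems = entry.validate()
        entry.usable = not entry.problems
        entries.append(entry)
    return entries


def select_content(
    entries: list[FeedEntry],
    wanted_identifier: str,
    wanted_version: Optional[str] = None,
    supported_format_version: str = FORMAT_VERSION,
) -> FeedEntry:
    """Pick the entry to install: compatible binary > source > fail."""
    usable = [
        e for e in entries
        if e.usable and e.content_item_identifier == wanted_identifier
    ]
    if wanted_version is not None:
        usable = [e for e in usable if e.content_item_version == wanted_version]
    if not usable:
        raise ContentUnavailable(
            f"{wanted_identifier} version {wanted_version or '(latest)'}"
        )
    if wanted_version is None:
        latest = max((e.content_item_version for e in usable), key=version_key)
        usable = [e for e in usable if e.content_item_version == latest]
    for e in usable:
        if (e.content_kind == "binary-index"
                and e.format_version == supported_format_version):
            return e
    for e in usable:
        if e.content_kind in ("rf2-source", "owl-source"):
            return e
    raise ContentUnavailable(
        f"{wanted_identifier} version "
        f"{wanted_version or usable[0].content_item_version}: no compatible "
        "binary index and no source files"
    )


class LocalTransport:
    """Resolves feed links against a local directory (or an in-memory map)."""

    def __init__(self, root=None, blobs: Optional[dict[str, bytes]] = None):
        self.root = Path(root) if root is not None else None
        self.blobs = blobs or {}

    def fetch(self, link: str) -> bytes:
        if link in self.blobs:
            return self.blobs[link]
        if self.root is not None:
            path = self.root / link
            if path.is_file():
                return path.read_bytes()
        raise ContentUnavailable(f"cannot fetch {link!r}")


def fetch_and_install(
    entry: FeedEntry, store: TerminologyStore, transport
) -> tuple[str, str, bool]:
    """Fetch an entry's payload, verify its checksum, install into the store.

    Returns ``(url, version, already_present)``; nothing is installed when
    verification fails. Re-installing an installed version is a no-op.
    """
    if not entry.usable:
        raise ContentUnavailable(
            f"entry {entry.entry_id} is unusable: {'; '.join(entry.problems)}"
        )
    key = (entry.content_item_identifier, entry.content_item_version)
    if key in store:
        return (*key, True)
    payload = transport.fetch(entry.link)
    digest = hashlib.sha256(payload).hexdigest()
    if digest != entry.checksum.lower():
        raise IntegrityError(
            f"checksum mismatch for {entry.link}: expected {entry.checksum}, "
            f"got {digest}"
        )
    if entry.content_kind == "binary-index":
        if entry.format_version != FORMAT_VERSION:
            raise IncompatibleIndexError(
                f"index format {entry.format_version!r} unsupported"
            )
        record = deserialize_binary_index(payload)
    elif entry.content_kind == "rf2-source":
        record = install_rf2_source(payload, *key)
    elif entry.content_kind == "owl-source":
        record = install_owl_source(payload)
    else:
        raise ContentUnavailable(f"unknown content kind {entry.content_kind!r}")
    store.add(record, validate=False)
    return (*key, False)


def generate_feed(
    store: TerminologyStore,
    selection: list[tuple[str, str, list[str]]],
    title: str = "termserve syndication feed",
    blobs: Optional[dict[str, bytes]] = None,
    out_dir=None,
) -> str:
    """Publish selected store content as an Atom feed.

    ``selection`` lists (url, version, kinds) with kinds drawn from
    ``binary-index`` / ``rf2-source``. Payloads are written into
    ``blobs`` (link -> bytes) and/or ``out_dir`` files; the returned XML
    carries relative links resolvable by :class:`LocalTransport`.
    """
    now = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    nsmap = {None: ATOM_NS, "ts": SYND_NS}
    feed = etree.Element(f"{{{ATOM_NS}}}feed", nsmap=nsmap)
    etree.SubElement(feed, f"{{{ATOM_NS}}}title").text = title
    etree.SubElement(feed, f"{{{ATOM_NS}}}id").text = "urn:termserve:feed"
    etree.SubElement(feed, f"{{{ATOM_NS}}}updated").text = now

    for url, version, kinds in selection:
        if (url, version) not in store:
            raise ContentUnavailable(f"{url} version {version} is not installed")
        record = store.code_systems[(url, version)]
        for kind in kinds:
            if kind == "binary-index":
                payload = serialize_binary_index(record)
            elif kind == "rf2-source":
                payload = serialize_rf2_source(record)
            else:
                raise ContentUnavailable(f"cannot generate kind {kind!r}")
            safe = (
                url.replace("://", "_").replace("/", "_").replace("?", "_")
                + f"_{version}_{kind}"
            )
            link = safe + (".index.json" if kind == "binary-index" else ".zip")
            if blobs is not None:
                blobs[link] = payload
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                (out / link).write_bytes(payload)

            entry = etree.SubElement(feed, f"{{{ATOM_NS}}}entry")
            etree.SubElement(entry, f"{{{ATOM_NS}}}id").text = (
                f"urn:termserve:{safe}"
            )
            etree.SubElement(entry, f"{{{ATOM_NS}}}title").text = (
                f"{record.name or url} {version} ({kind})"
            )
            etree.SubElement(entry, f"{{{ATOM_NS}}}updated").text = now
            etree.SubElement(
                entry, f"{{{ATOM_NS}}}category",
                scheme=SYND_NS + "#content-kind", term=kind,
            )
            etree.SubElement(entry, f"{{{ATOM_NS}}}link", href=link)
            etree.SubElement(
                entry, f"{{{SYND_NS}}}contentItemIdentifier"
            ).text = url
            etree.SubElement(
                entry, f"{{{SYND_NS}}}contentItemVersion"
            ).text = version
            etree.SubElement(entry, f"{{{SYND_NS}}}formatVersion").text = (
                FORMAT_VERSION if kind == "binary-index" else ""
            )
            etree.SubElement(entry, f"{{{SYND_NS}}}checksum").text = (
                hashlib.sha256(payload).hexdigest()
            )
    return etree.tostring(
        feed, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")
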