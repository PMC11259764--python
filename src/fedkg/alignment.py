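"""Privacy-preserving patient alignment via salted, hashed identities.

Identities are normalized, then digested with SHA-256 over a consortium
shared salt, so that equality of ciphertext digests — and nothing else —
links the same patient across hospitals.  The salt is distributed out of
band through configuration and blocks dictionary attacks on low-entropy
citizen identifiers.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional


class IdentityError(ValueError):
    """Identity empty or unusable after normalization."""


class SaltMismatchError(RuntimeError):
    """Parties attempted alignment under different salts: no partial match."""


def normalize_identity(raw: str) -> str:
    """Canonical identity: trimmed, uppercased, whitespace/hyphens removed."""
    if raw is None:
        raise IdentityError("identity is None")
    canonical = "".join(ch for ch in str(raw) if not ch.isspace() and ch != "-").upper()
    if not canonical:
        raise IdentityError(f"identity {raw!r} empty after normalization")
    return canonical


@dataclass(frozen=True)
class HashedIdentity:
    digest: str  # 64 lowercase hex chars
    salt_id: str

    def __post_init__(self):
        if len(self.digest) != 64 or any(c not in "0123456789abcdef" for c in self.digest):
            raise IdentityError("digest must be 64 lowercase hex characters")


def hash_identity(identity: str, salt: str, salt_id: str = "consortium") -> HashedIdentity:
    """SHA-256(salt || normalized identity) as lowercase hex."""
    canonical = normalize_identity(identity)
    digest = hashlib.sha256((salt + canonical).encode("utf-8")).hexdigest()
    return HashedIdentity(digest=digest, salt_id=salt_id)


@dataclass(frozen=True)
class AlignmentEntry:
    digest: str
    hospital_id: str
    person_uri: str


@dataclass(frozen=True)
class AlignmentTable:
    """Digest-equality matches between local patients and remote subgraphs.

    ``entries`` holds local person resources matched to a remote digest;
    ``unmatched_remote`` retains digests seen in subgraphs with no local
    counterpart (kept for audit); ``collisions`` lists digests claimed by
    two distinct local identities — flagged and held out, never merged.
    """

    entries: tuple[AlignmentEntry, ...] = ()
    unmatched_remote: tuple[str, ...] = ()
    collisions: tuple[str, ...] = ()

    def matched_digests(self) -> frozenset[str]:
        return frozenset(e.digest for e in self.entries)

    def local_for(self, digest: str) -> Optional[str]:
        for e in self.entries:
            if e.digest == digest:
                return e.person_uri
        return None

    def to_rows(self) -> list[dict]:
        return [
            {"digest": e.digest, "hospital_id": e.hospital_id, "person_uri": e.person_uri}
            for e in self.entries
        ]


def align_patients(
    local_digests: Mapping[str, HashedIdentity],
    subgraphs: Iterable,
    local_hospital_id: str,
    local_identities: Optional[Mapping[str, str]] = None,
) -> AlignmentTable:
    """Match local patients to the hashed identities of incoming subgraphs.

    ``local_digests`` maps local person resource URIs to their hashed
    identities; ``subgraphs`` are deserialized online subgraphs carrying a
    ``digest`` and ``salt_id``.  All parties must share the same salt_id;
    a mismatch aborts with no partial matching.  When ``local_identities``
    (person URI -> normalized identity) is supplied, a digest produced by
    two distinct local identities is flagged as a collision and withheld.
    """
    salt_ids = {h.salt_id for h in local_digests.values()}
    if len(salt_ids) > 1:
        raise SaltMismatchError(f"local digests mix salt_ids {sorted(salt_ids)}")
    local_salt = salt_ids.pop() if salt_ids else None

    remote_digests: set[str] = set()
    for sg in subgraphs:
        if local_salt is not None and sg.salt_id != local_salt:
            raise SaltMismatchError(
                f"subgraph from {sg.origin_hospital_id!r} uses salt_id "
                f"{sg.salt_id!r}, local salt_id is {local_salt!r}"
            )
        remote_digests.add(sg.digest)

    by_digest: dict[str, list[str]] = {}
    for uri in sorted(local_digests):
        by_digest.setdefault(local_digests[uri].digest, []).append(uri)

    collisions: list[str] = []
    entries: list[AlignmentEntry] = []
    for digest in sorted(by_digest):
        uris = by_digest[digest]
        if local_identities is not None:
            identities = {local_identities[u] for u in uris if u in local_identities}
            if len(identities) > 1:
                collisions.append(digest)
                continue
        if digest in remote_digests:
            for uri in uris:
                entries.append(
                    AlignmentEntry(
                        digest=digest, hospital_id=local_hospital_id, person_uri=uri
                    )
                )
    unmatched = sorted(remote_digests - set(by_digest))
    return AlignmentTable(
        entries=tuple(entries),
        unmatched_remote=tuple(unmatched),
        collisions=tuple(sorted(collisions)),
    )
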