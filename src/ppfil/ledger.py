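"""Hash-chained model ledger with accuracy-gated admission and
proof-of-contribution scoring.

Blocks carry a SHA-256 digest of the serialized global parameter vector
plus round metadata — parameters themselves stay off-chain. Hashing is over
a canonical key-sorted, compact, UTF-8 JSON encoding; floats in payloads
are rounded to 12 significant digits first so digests are platform-stable.
A block is admitted only if the round's validation accuracy clears the
ledger's threshold; timestamps are logical round counters, keeping chains
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "Block",
    "Ledger",
    "ContributionRecord",
    "compute_block_hash",
    "append_block",
    "validate_chain",
    "poc_score",
    "select_proposer",
    "digest_params",
]

GENESIS_HASH = "0" * 64


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def canonical_json(obj) -> bytes:
    """Key-sorted, compact-separator, UTF-8 JSON with 12-sig-digit floats."""
    try:
        return json.dumps(
            _round_floats(obj), sort_keys=True, separators=(",", ":"), ensure_ascii=False
        ).encode("utf-8")
    except TypeError as exc:
        raise ValueError(f"payload is not serializable: {exc}") from exc


def digest_params(params: np.ndarray) -> str:
    """SHA-256 digest of a parameter vector (12-sig-digit canonical form)."""
    return hashlib.sha256(canonical_json(list(np.asarray(params, float)))).hexdigest()


@dataclass
class Block:
    index: int
    timestamp: int  # logical round counter
    payload: dict
    previous_hash: str
    hash: str = ""


@dataclass
class ContributionRecord:
    client_id: int
    round: int
    score: float
    cumulative: float


def compute_block_hash(block: Block) -> str:
    """SHA-256 over the canonical encoding of all fields except the hash."""
    body = {
        "index": block.index,
        "timestamp": block.timestamp,
        "payload": block.payload,
        "previous_hash": block.previous_hash,
    }
    return hashlib.sha256(canonical_json(body)).hexdigest()


@dataclass
class Ledger:
    blocks: list[Block] = field(default_factory=list)
    threshold: float = 0.0  # minimum validation accuracy for admission

    @property
    def head_hash(self) -> str:
        return self.blocks[-1].hash if self.blocks else GENESIS_HASH

    def __len__(self) -> int:
        return len(self.blocks)

    def contributions(self) -> list[ContributionRecord]:
        out = []
        for b in self.blocks:
            for rec in b.payload.get("contributions", []):
                out.append(ContributionRecord(**rec))
        return out

    def export_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for b in self.blocks:
                fh.write(canonical_json(asdict(b)).decode("utf-8") + "\n")

    @classmethod
    def import_jsonl(cls, path: str | Path, threshold: float = 0.0) -> "Ledger":
        blocks = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    blocks.append(Block(**json.loads(line)))
        return cls(blocks=blocks, threshold=threshold)


def append_block(
    ledger: Ledger, payload: dict, validation_accuracy: float, timestamp: int | None = None
) -> bool:
    """Admit a block iff the validation accuracy clears the threshold.

    Returns True on admission; a rejected update leaves the chain (and head
    hash) untouched.
    """
    ok, bad = validate_chain(ledger)
    if not ok:
        raise ValueError(f"chain invalid at block {bad}; refusing to append")
    if validation_accuracy < ledger.threshold:
        return False
    block = Block(
        index=len(ledger.blocks),
        timestamp=len(ledger.blocks) if timestamp is None else timestamp,
        payload=dict(payload, validation_accuracy=validation_accuracy),
        previous_hash=ledger.head_hash,
    )
    block.hash = compute_block_hash(block)
    ledger.blocks.append(block)
    return True


def validate_chain(ledger: Ledger) -> tuple[bool, int | None]:
    """Check every stored hash recomputes and every link matches.

    Returns (True, None) for a valid chain, else (False, earliest bad index).
    The hash-recompute check runs before the successor's link check, so a
    tampered stored hash is reported at its own block.
    """
    prev = GENESIS_HASH
    for i, b in enumerate(ledger.blocks):
        if b.hash != compute_block_hash(b):
            return False, i
        if b.previous_hash != prev:
            return False, i
        prev = b.hash
    return True, None


def poc_score(global_with: float, global_without: float) -> float:
    """Proof-of-contribution: leave-one-out marginal validation-accuracy
    gain, floored at zero (harmful updates earn nothing)."""
    if not (0 <= global_with <= 1 and 0 <= global_without <= 1):
        raise ValueError("accuracies must lie in [0, 1]")
    return max(0.0, global_with - global_without)


def select_proposer(records: list[ContributionRecord]) -> int:
    """Client with the highest cumulative contribution; ties -> lowest id."""
    if not records:
        raise ValueError("no contribution records")
    latest: dict[int, float] = {}
    for r in records:
        latest[r.client_id] = r.cumulative
    best = max(latest.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]
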