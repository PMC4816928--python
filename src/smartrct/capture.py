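"""Shopping-data capture: scans, electronic lists, receipts, label views.

The app runs two simultaneous modes. *Data collection* (weeks 1–5):
every scan appends an item to the participant's open electronic list,
which is later transmitted to the trial database. *Intervention
delivery* (weeks 2–5): a scan of a product matched in the food database
additionally returns the participant's allocated nutrition label plus a
random selection of same-category products, and logs a label-view
event. Unmatched barcodes yield a not-found outcome offering a
crowdsource submission (photo metadata only; images are out of scope).

Till-receipt photographs are stored as metadata records linked to a
transmitted list. Outcome exports are keyed by participant id only —
no e-mail fingerprints or free-text identity fields ever enter them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, StateError
from .food_db import FoodDatabase, match_barcode, related_products
from .labels import Label, label_for

if TYPE_CHECKING:  # pragma: no cover
    from .config import TrialConfig
    from .trial import Participant

MODE_COLLECTION = "collection"
MODE_INTERVENTION = "intervention"


@dataclass
class ScanEvent:
    participant_id: str
    barcode: str
    day: int
    matched: bool
    mode: str


@dataclass
class ListItem:
    barcode: str
    quantity: int = 1
    matched: bool = True


@dataclass
class ShoppingList:
    list_id: str
    participant_id: str
    items: list[ListItem] = field(default_factory=list)
    submitted_day: Optional[int] = None
    transmitted: bool = False
    receipt_ids: list[str] = field(default_factory=list)

    @property
    def total_quantity(self) -> int:
        return sum(item.quantity for item in self.items)


@dataclass
class ReceiptMeta:
    receipt_id: str
    participant_id: str
    day: int
    list_id: str


@dataclass
class LabelViewEvent:
    participant_id: str
    barcode: str
    arm: str
    day: int


@dataclass
class CrowdsourceSubmission:
    participant_id: str
    barcode: str
    photo_count: int
    day: int


@dataclass
class ScanOutcome:
    """What the app shows after one scan."""

    matched: bool
    mode: str
    barcode: str
    label: Optional[Label] = None
    related: list = field(default_factory=list)
    crowdsource_offered: bool = False


class CaptureStore:
    """Event store for one trial run; one open list per participant."""

    def __init__(self, related_n: int = 4, rng: Optional[np.random.Generator] = None):
        self.related_n = related_n
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.scans: list[ScanEvent] = []
        self.lists: list[ShoppingList] = []          # transmitted history
        self.open_lists: dict[str, ShoppingList] = {}
        self.receipts: list[ReceiptMeta] = []
        self.label_views: list[LabelViewEvent] = []
        self.crowdsource: list[CrowdsourceSubmission] = []
        self._list_seq: dict[str, int] = {}
        self._unmatched: set[tuple[str, str]] = set()  # (pid, barcode) seen unmatched

    # -- scanning -----------------------------------------------------------

    def _open_list(self, participant_id: str) -> ShoppingList:
        if participant_id not in self.open_lists:
            seq = self._list_seq.get(participant_id, 0) + 1
            self._list_seq[participant_id] = seq
            self.open_lists[participant_id] = ShoppingList(
                list_id=f"{participant_id}-L{seq:04d}", participant_id=participant_id)
        return self.open_lists[participant_id]

    def scan(self, participant: "Participant", barcode: str, db: FoodDatabase,
             config: "TrialConfig", clock: int, quantity: int = 1) -> ScanOutcome:
        """Record one barcode scan and return what the app would display.

        Collection behaviour (always): the item joins the open list.
        Intervention behaviour (post-randomization, matched product):
        additionally returns the allocated label and related products
        and logs a label view.
        """
        from .trial import State

        if participant.state not in (State.BASELINE, State.INTERVENTION):
            raise StateError(
                f"participant {participant.id} cannot scan in state {participant.state.name}")
        mode = MODE_INTERVENTION if participant.state is State.INTERVENTION else MODE_COLLECTION

        product = match_barcode(db, barcode)
        matched = product is not None
        self.scans.append(ScanEvent(participant.id, barcode, clock, matched, mode))
        self._open_list(participant.id).items.append(
            ListItem(barcode=barcode, quantity=quantity, matched=matched))

        outcome = ScanOutcome(matched=matched, mode=mode, barcode=barcode)
        if not matched:
            self._unmatched.add((participant.id, barcode))
            outcome.crowdsource_offered = True
            return outcome
        if mode == MODE_INTERVENTION:
            outcome.label = label_for(product, participant.arm, config)
            outcome.related = related_products(db, product, self.related_n, self.rng)
            self.label_views.append(LabelViewEvent(participant.id, barcode, participant.arm, clock))
        return outcome

    def submit_crowdsource(self, participant: "Participant", barcode: str,
                           clock: int, photo_count: int = 1) -> CrowdsourceSubmission:
        """File a missing-product submission; only valid after an unmatched scan."""
        if (participant.id, barcode) not in self._unmatched:
            raise StateError(f"barcode {barcode} was never unmatched for {participant.id}")
        sub = CrowdsourceSubmission(participant.id, barcode, photo_count, clock)
        self.crowdsource.append(sub)
        return sub

    # -- lists and receipts -------------------------------------------------

    def submit_list(self, participant: "Participant", clock: int,
                    transmitted: bool = True) -> ShoppingList:
        """Transmit the open list to the trial database.

        On transmission failure the list stays open for retry, so a
        retried submission yields exactly one history entry.
        """
        open_list = self.open_lists.get(participant.id)
        if open_list is None or not open_list.items:
            raise StateError(f"participant {participant.id} has no non-empty open list")
        if not transmitted:
            return open_list
        open_list.submitted_day = clock
        open_list.transmitted = True
        self.lists.append(open_list)
        del self.open_lists[participant.id]
        return open_list

    def add_receipt(self, participant: "Participant", clock: int, list_id: str) -> ReceiptMeta:
        if all(lst.list_id != list_id for lst in self.lists):
            raise StateError(f"list {list_id} not in transmitted history")
        receipt = ReceiptMeta(f"R{len(self.receipts) + 1:05d}", participant.id, clock, list_id)
        self.receipts.append(receipt)
        for lst in self.lists:
            if lst.list_id == list_id:
                lst.receipt_ids.append(receipt.receipt_id)
        return receipt

    def last_list_day(self, participant_id: str) -> Optional[int]:
        days = [lst.submitted_day for lst in self.lists if lst.participant_id == participant_id]
        return max(days) if days else None

    def items_submitted_between(self, participant_id: str, start: int, end: int) -> int:
        """Total item quantity over lists transmitted on days [start, end)."""
        return sum(lst.total_quantity for lst in self.lists
                   if lst.participant_id == participant_id
                   and lst.submitted_day is not None and start <= lst.submitted_day < end)


def export_outcomes(store: CaptureStore, out_dir: str | Path, format: str = "csv") -> dict[str, Path]:
    """Write the five outcome streams, keyed by participant id only.

    Streams: lists, items, receipts, label_views, crowdsource. Output
    ordering is deterministic, so repeated exports are byte-identical.
    """
    if format not in ("csv", "jsonl"):
        raise FormatError(f"unknown export format {format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lists_rows = [{
        "list_id": lst.list_id, "participant_id": lst.participant_id,
        "submitted_day": lst.submitted_day, "n_items": len(lst.items),
        "total_quantity": lst.total_quantity,
    } for lst in store.lists]
    items_rows = [{
        "list_id": lst.list_id, "participant_id": lst.participant_id,
        "barcode": item.barcode, "quantity": item.quantity, "matched": item.matched,
    } for lst in store.lists for item in lst.items]
    receipts_rows = [asdict(r) for r in store.receipts]
    views_rows = [asdict(v) for v in store.label_views]
    crowd_rows = [asdict(c) for c in store.crowdsource]

    streams = {
        "lists": (lists_rows, ["participant_id", "list_id"]),
        "items": (items_rows, ["participant_id", "list_id", "barcode"]),
        "receipts": (receipts_rows, ["participant_id", "receipt_id"]),
        "label_views": (views_rows, ["participant_id", "day", "barcode"]),
        "crowdsource": (crowd_rows, ["participant_id", "day", "barcode"]),
    }
    paths: dict[str, Path] = {}
    for name, (rows, sort_keys) in streams.items():
        df = pd.DataFrame(rows)
        if not df.empty:
            df = df.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)
        if format == "csv":
            path = out_dir / f"{name}.csv"
            df.to_csv(path, index=False)
        else:
            path = out_dir / f"{name}.jsonl"
            with open(path, "w") as fh:
                for rec in df.to_dict(orient="records"):
                    fh.write(json.dumps(rec) + "\n")
        paths[name] = path
    return paths
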