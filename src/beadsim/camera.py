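"""Capture-on-message camera service.

The instrument-control pattern simulated here: the liquid handler and the
camera host are separate machines on one LAN; every time the protocol wants
a picture it sends a small serialized message, and the camera host answers
by grabbing a frame, writing it to the output folder and acknowledging with
the filename.  The wire format is newline-delimited JSON over a local TCP
stream; frames are 8-bit RGB (default 640 x 480) saved as lossless PNG with
a CSV index row per file.

A :class:`MockCameraSource` stands in for the USB camera and can be backed
by the synthetic scene renderer, so the whole request -> capture -> file
loop is testable without hardware; the same server code would wrap a real
frame grabber by swapping the source object.
"""

from __future__ import annotations

import csv
import json
import socket
import socketserver
import threading
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional

import numpy as np
from PIL import Image

__all__ = [
    "CaptureMessage",
    "ImageRecord",
    "DecodeError",
    "AcquisitionError",
    "encode_message",
    "decode_message",
    "MockCameraSource",
    "capture",
    "CaptureService",
    "CameraServer",
    "send_message",
    "INDEX_FILENAME",
]

INDEX_FILENAME = "index.csv"
_INDEX_FIELDS = ["filename", "run_id", "slot", "well", "sim_time", "sequence", "capture_wall_time"]


class DecodeError(ValueError):
    """Bytes on the wire did not decode to a valid message."""

    def __init__(self, message: str, payload: bytes = b""):
        self.payload = payload
        super().__init__(message)


class AcquisitionError(RuntimeError):
    """The camera source could not deliver a frame."""


@dataclass(frozen=True)
class CaptureMessage:
    """One capture request; ``sequence`` must increase strictly within a run."""

    run_id: str
    well: str
    slot: int
    sim_time: float
    sequence: int

    def __post_init__(self):
        if self.sequence < 0:
            raise ValueError("sequence must be >= 0")


@dataclass(frozen=True)
class ImageRecord:
    filename: str
    run_id: str
    slot: int
    well: str
    sim_time: float
    sequence: int
    capture_wall_time: float


def encode_message(msg: CaptureMessage) -> bytes:
    """Serialize to one newline-terminated JSON line."""
    return (json.dumps(asdict(msg), sort_keys=True) + "\n").encode("utf-8")


def decode_message(data: bytes) -> CaptureMessage:
    """Inverse of :func:`encode_message`; raises DecodeError with the payload."""
    if not data or not data.strip():
        raise DecodeError("empty payload", data)
    try:
        doc = json.loads(data.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise DecodeError(f"not valid JSON: {exc}", data) from exc
    if not isinstance(doc, dict):
        raise DecodeError("message must be a JSON object", data)
    try:
        return CaptureMessage(
            run_id=str(doc["run_id"]),
            well=str(doc["well"]),
            slot=int(doc["slot"]),
            sim_time=float(doc["sim_time"]),
            sequence=int(doc["sequence"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DecodeError(f"malformed message fields: {exc}", data) from exc


# ---------------------------------------------------------------------------
# Camera sources

class MockCameraSource:
    """A virtual camera delivering frames from a scene callback or fixed image.

    ``scene`` may be a ready (H, W, 3) uint8 array or a zero-argument callable
    returning one (e.g. a closure over the synthetic renderer and a simulated
    clock).  Resolution defaults to 640 x 480; a frame of any other shape than
    configured raises, so resolution is an explicit contract.
    """

    def __init__(
        self,
        scene: Optional[object] = None,
        width: int = 640,
        height: int = 480,
    ):
        self.width = width
        self.height = height
        self._scene = scene
        self._open = True

    def close(self) -> None:
        self._open = False

    def read(self) -> np.ndarray:
        if not self._open:
            raise AcquisitionError("camera source is closed")
        scene = self._scene
        frame = scene() if callable(scene) else scene
        if frame is None:
            frame = np.zeros((self.height, self.width, 3), dtype=np.uint8)
        frame = np.asarray(frame)
        if frame.shape != (self.height, self.width, 3):
            raise AcquisitionError(
                f"source produced shape {frame.shape}, configured "
                f"({self.height}, {self.width}, 3)"
            )
        if frame.dtype != np.uint8:
            raise AcquisitionError(f"source produced dtype {frame.dtype}, need uint8")
        return frame


def capture(source: MockCameraSource) -> np.ndarray:
    """Acquire one (H, W, 3) uint8 frame from an open source."""
    return source.read()


# ---------------------------------------------------------------------------
# Capture service (transport-independent core)

class CaptureService:
    """Handles decoded capture requests: one PNG + one index row per request.

    Shared by the TCP server and by in-process replay.  Tracks the last
    sequence number per run and rejects regressions.  When ``latest_frame``
    is enabled, each capture also overwrites ``latest.png`` (the headless
    stand-in for a live-feed window).
    """

    def __init__(
        self,
        source: MockCameraSource,
        out_dir,
        latest_frame: bool = False,
        clock: Callable[[], float] = time.time,
    ):
        self.source = source
        self.out_dir = Path(out_dir)
        self.latest_frame = latest_frame
        self.clock = clock
        self._last_sequence: dict[str, int] = {}
        self._lock = threading.Lock()
        try:
            self.out_dir.mkdir(parents=True, exist_ok=True)
            probe = self.out_dir / ".writable"
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise AcquisitionError(f"output folder not writable: {exc}") from exc
        self.index_path = self.out_dir / INDEX_FILENAME
        if not self.index_path.exists():
            with open(self.index_path, "w", newline="") as fh:
                csv.DictWriter(fh, fieldnames=_INDEX_FIELDS).writeheader()

    def handle_line(self, line: bytes) -> dict:
        """Process one wire line; returns the JSON-able reply dict."""
        try:
            msg = decode_message(line)
        except DecodeError as exc:
            return {"status": "error", "reason": str(exc)}
        try:
            record = self.handle_message(msg)
        except (AcquisitionError, ValueError, OSError) as exc:
            return {"status": "error", "reason": str(exc)}
        return {"status": "ok", "filename": record.filename}

    def handle_message(self, msg: CaptureMessage) -> ImageRecord:
        with self._lock:
            last = self._last_sequence.get(msg.run_id)
            if last is not None and msg.sequence <= last:
                raise ValueError(
                    f"sequence regression: got {msg.sequence} after {last} "
                    f"in run {msg.run_id!r}"
                )
            frame = capture(self.source)
            filename = f"{msg.run_id}_{msg.slot}_{msg.well}_{msg.sequence:05d}.png"
            path = self.out_dir / filename
            Image.fromarray(frame, mode="RGB").save(path, format="PNG")
            if self.latest_frame:
                Image.fromarray(frame, mode="RGB").save(self.out_dir / "latest.png")
            record = ImageRecord(
                filename=filename,
                run_id=msg.run_id,
                slot=msg.slot,
                well=msg.well,
                sim_time=msg.sim_time,
                sequence=msg.sequence,
                capture_wall_time=float(self.clock()),
            )
            with open(self.index_path, "a", newline="") as fh:
                csv.DictWriter(fh, fieldnames=_INDEX_FIELDS).writerow(asdict(record))
            self._last_sequence[msg.run_id] = msg.sequence
            return record

    def replay(self, lines: Iterable[bytes]) -> list[dict]:
        """In-process equivalent of a client session; returns replies."""
        return [self.handle_line(line) for line in lines]


# ---------------------------------------------------------------------------
# TCP transport

class _Handler(socketserver.StreamRequestHandler):
    def handle(self):
        service: CaptureService = self.server.service  # type: ignore[attr-defined]
        for raw in self.rfile:
            reply = service.handle_line(raw)
            self.wfile.write((json.dumps(reply) + "\n").encode("utf-8"))
            self.wfile.flush()


class CameraServer(socketserver.ThreadingTCPServer):
    """Newline-JSON capture server bound to ``(host, port)``.

    Use ``port=0`` for an ephemeral port (``server_address`` reports the
    bound one).  ``start_background()`` serves on a daemon thread.
    """

    allow_reuse_address = True
    daemon_threads = True

    def __init__(self, endpoint: tuple[str, int], service: CaptureService):
        super().__init__(endpoint, _Handler)
        self.service = service

    def start_background(self) -> threading.Thread:
        thread = threading.Thread(target=self.serve_forever, daemon=True)
        thread.start()
        return thread


def send_message(endpoint: tuple[str, int], msg: CaptureMessage, timeout: float = 10.0) -> dict:
    """Send one capture request and return the decoded acknowledgement."""
    with socket.create_connection(endpoint, timeout=timeout) as sock:
        sock.sendall(encode_message(msg))
        fh = sock.makefile("rb")
        line = fh.readline()
    if not line:
        raise DecodeError("connection closed without acknowledgement")
    return json.loads(line.decode("utf-8"))
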