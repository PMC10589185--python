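"""Session management over byte streams plus the frame-counting latency harness.

Two transports share one framing code path: a TCP client/server pair (the
planner connects to the reslice server through a known hostname and port) and
an in-process loopback queue pair so protocol tests need no network.  The
latency harness mirrors a slow-motion-video frame-counting methodology:
round-trip durations are converted to frame counts at a given capture rate
(120 Hz by default) and summarised by quantiles and the fraction of trials
within a frame budget.
"""

from __future__ import annotations

import math
import socket
import threading
import time
from collections import deque
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import FramingError, TimeoutError_
from .messages import HEADER_SIZE, decode_header

DEFAULT_TIMEOUT_S = 5.0


@dataclass(frozen=True)
class Endpoint:
    role: str  # "server" | "client"
    hostname: str = "127.0.0.1"
    port: int = 18944


class FrameAssembler:
    """Reassembles whole messages from arbitrarily chunked stream bytes."""

    def __init__(self) -> None:
        self._buffer = bytearray()
        self._ready: deque[bytes] = deque()

    def feed(self, chunk: bytes) -> None:
        self._buffer.extend(chunk)
        while True:
            if len(self._buffer) < HEADER_SIZE:
                return
            header = decode_header(bytes(self._buffer[:HEADER_SIZE]))
            total = HEADER_SIZE + header.body_size
            if len(self._buffer) < total:
                return
            self._ready.append(bytes(self._buffer[:total]))
            del self._buffer[:total]

    def pop(self) -> bytes | None:
        return self._ready.popleft() if self._ready else None


class Session:
    """Ordered, whole-message channel; concrete transports implement _send/_recv."""

    def send(self, message: bytes) -> None:
        raise NotImplementedError

    def receive(self, timeout: float | None = DEFAULT_TIMEOUT_S) -> bytes:
        raise NotImplementedError

    def close(self) -> None:  # pragma: no cover - trivial default
        pass

    def __enter__(self) -> "Session":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


class LoopbackSession(Session):
    """One end of a same-process queue pair; bytes still pass the framing path."""

    def __init__(self, chunk_size: int | None = None) -> None:
        self._assembler = FrameAssembler()
        self._lock = threading.Lock()
        self._cond = threading.Condition(self._lock)
        self.peer: "LoopbackSession" | None = None
        self._chunk_size = chunk_size

    def _feed(self, data: bytes) -> None:
        with self._cond:
            self._assembler.feed(data)
            self._cond.notify_all()

    def send(self, message: bytes) -> None:
        assert self.peer is not None, "loopback session is unpaired"
        step = self._chunk_size or len(message) or 1
        for start in range(0, len(message), step):
            self.peer._feed(message[start : start + step])

    def receive(self, timeout: float | None = DEFAULT_TIMEOUT_S) -> bytes:
        deadline = None if timeout is None else time.monotonic() + timeout
        with self._cond:
            while True:
                message = self._assembler.pop()
                if message is not None:
                    return message
                remaining = None if deadline is None else deadline - time.monotonic()
                if remaining is not None and remaining <= 0:
                    raise TimeoutError_("receive timed out")
                self._cond.wait(remaining)


def loopback_pair(chunk_size: int | None = None) -> tuple[LoopbackSession, LoopbackSession]:
    """Two connected in-process sessions (optionally chunking sends)."""
    a, b = LoopbackSession(chunk_size), LoopbackSession(chunk_size)
    a.peer, b.peer = b, a
    return a, b


class SocketSession(Session):
    def __init__(self, sock: socket.socket) -> None:
        self._sock = sock
        self._assembler = FrameAssembler()

    def send(self, message: bytes) -> None:
        self._sock.sendall(message)

    def receive(self, timeout: float | None = DEFAULT_TIMEOUT_S) -> bytes:
        deadline = None if timeout is None else time.monotonic() + timeout
        while True:
            message = self._assembler.pop()
            if message is not None:
                return message
            if deadline is not None:
                remaining = deadline - time.monotonic()
                if remaining <= 0:
                    raise TimeoutError_("receive timed out")
                self._sock.settimeout(remaining)
            else:
                self._sock.settimeout(None)
            try:
                chunk = self._sock.recv(65536)
            except socket.timeout as exc:
                raise TimeoutError_("receive timed out") from exc
            if not chunk:
                raise FramingError("connection closed mid-stream")
            self._assembler.feed(chunk)

    def close(self) -> None:
        try:
            self._sock.shutdown(socket.SHUT_RDWR)
        except OSError:
            pass
        self._sock.close()


Handler = Callable[[bytes], bytes | None]


class Server:
    """TCP server dispatching each whole message to a handler.

    The handler receives encoded message bytes and may return reply bytes
    (e.g. the reslice server answers a TRANSFORM with an IMAGE).  A handler
    error on one message does not tear down the connection.
    """

    def __init__(self, endpoint: Endpoint, handler: Handler) -> None:
        self.endpoint = endpoint
        self.handler = handler
        self._listener: socket.socket | None = None
        self._threads: list[threading.Thread] = []
        self._running = False
        self.port: int = endpoint.port

    def start(self) -> "Server":
        sock = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        sock.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        sock.bind((self.endpoint.hostname, self.endpoint.port))
        sock.listen(4)
        self.port = sock.getsockname()[1]
        self._listener = sock
        self._running = True
        thread = threading.Thread(target=self._accept_loop, daemon=True)
        thread.start()
        self._threads.append(thread)
        return self

    def _accept_loop(self) -> None:
        assert self._listener is not None
        while self._running:
            try:
                conn, _addr = self._listener.accept()
            except OSError:
                return
            thread = threading.Thread(target=self._serve_client, args=(conn,), daemon=True)
            thread.start()
            self._threads.append(thread)

    def _serve_client(self, conn: socket.socket) -> None:
        session = SocketSession(conn)
        try:
            while self._running:
                try:
                    message = session.receive(timeout=None)
                except FramingError:
                    return
                reply = self.handler(message)
                if reply is not None:
                    session.send(reply)
        finally:
            session.close()

    def stop(self) -> None:
        self._running = False
        if self._listener is not None:
            self._listener.close()

    def __enter__(self) -> "Server":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def serve(endpoint: Endpoint, handler: Handler) -> Server:
    """Start a TCP server; returns the running server (use .stop() or a with-block)."""
    return Server(endpoint, handler).start()


def connect(endpoint: Endpoint, timeout: float = DEFAULT_TIMEOUT_S) -> SocketSession:
    sock = socket.create_connection((endpoint.hostname, endpoint.port), timeout=timeout)
    return SocketSession(sock)


def attach_loopback(handler: Handler, chunk_size: int | None = None) -> LoopbackSession:
    """Client session whose peer dispatches every message to ``handler`` inline."""
    client, server_side = loopback_pair(chunk_size)

    class _Dispatch(LoopbackSession):
        def _feed(self, data: bytes) -> None:
            with self._cond:
                self._assembler.feed(data)
            while True:
                message = self._assembler.pop()
                if message is None:
                    return
                reply = handler(message)
                if reply is not None:
                    client._feed(reply)

    dispatcher = _Dispatch(chunk_size)
    dispatcher.peer = client
    client.peer = dispatcher
    return client


# ---------------------------------------------------------------------------
# frame/ms arithmetic and the latency report


def frames_to_ms(frames: float, capture_rate_hz: float) -> float:
    """Duration spanned by ``frames`` video frames at the capture rate."""
    if capture_rate_hz <= 0:
        raise ValueError("capture rate must be positive")
    return 1000.0 * frames / capture_rate_hz


def ms_to_frames(duration_ms: float, capture_rate_hz: float) -> int:
    """Number of whole frames covering a duration (ceiling inverse of frames_to_ms)."""
    if capture_rate_hz <= 0:
        raise ValueError("capture rate must be positive")
    return math.ceil(duration_ms * capture_rate_hz / 1000.0 - 1e-9)


@dataclass
class LatencyReport:
    """Round-trip latency summary in the frame-counting idiom."""

    durations_ms: list[float | None]
    capture_rate_hz: float = 120.0
    frame_budget: int = 6

    @property
    def completed(self) -> list[float]:
        return [d for d in self.durations_ms if d is not None]

    @property
    def n_missing(self) -> int:
        return sum(1 for d in self.durations_ms if d is None)

    @property
    def frame_counts(self) -> list[int]:
        return [ms_to_frames(d, self.capture_rate_hz) for d in self.completed]

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.completed, q))

    def fraction_within_frames(self, budget: int | None = None) -> float:
        budget = self.frame_budget if budget is None else budget
        counts = self.frame_counts
        if not counts:
            return math.nan
        return sum(1 for c in counts if c <= budget) / len(counts)

    def summary(self) -> dict:
        done = self.completed
        counts = self.frame_counts
        out = {
            "n_trials": len(self.durations_ms),
            "n_missing": self.n_missing,
            "capture_rate_hz": self.capture_rate_hz,
            "frame_budget": self.frame_budget,
        }
        if done:
            out.update(
                {
                    "median_ms": float(np.median(done)),
                    "p80_ms": self.quantile(0.8),
                    "max_ms": float(np.max(done)),
                    "p80_frames": int(np.quantile(counts, 0.8, method="inverted_cdf")),
                    "fraction_within_budget": self.fraction_within_frames(),
                    "budget_ms": frames_to_ms(self.frame_budget, self.capture_rate_hz),
                }
            )
        return out


def measure_roundtrip(
    session: Session,
    n_trials: int,
    payload_factory: Callable[[int], bytes],
    capture_rate_hz: float = 120.0,
    frame_budget: int = 6,
    timeout: float = DEFAULT_TIMEOUT_S,
) -> LatencyReport:
    """Send ``n_trials`` messages and time each full request/reply exchange.

    A trial that times out is recorded as missing rather than aborting the run.
    """
    durations: list[float | None] = []
    for trial in range(n_trials):
        message = payload_factory(trial)
        start = time.perf_counter()
        session.send(message)
        try:
            session.receive(timeout=timeout)
        except TimeoutError_:
            durations.append(None)
            continue
        durations.append((time.perf_counter() - start) * 1000.0)
    return LatencyReport(durations, capture_rate_hz=capture_rate_hz, frame_budget=frame_budget)
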