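"""Publish-subscribe broadcast of aggregates to detached viewers.

The master publishes complete aggregate snapshots over TCP; any number of
subscribers (headless consumers, plotting front ends) may attach or detach
at any time.  Publishing is strictly non-blocking for the master: each
subscriber gets its own bounded outgoing queue drained by a sender thread,
and when a subscriber is slow or dead its oldest pending messages are
dropped (live monitoring wants the newest state, not a backlog).

Wire format: a 4-byte big-endian length prefix followed by a UTF-8 JSON
document.  NumPy arrays are tagged objects carrying dtype, shape and
base64-encoded raw bytes, so a round trip on one platform is bit-exact.
"""

from __future__ import annotations

import base64
import json
import queue
import socket
import struct
import threading
from typing import Any

import numpy as np

__all__ = ["encode_message", "decode_message", "Publisher", "Subscriber"]

_HDR = struct.Struct(">I")


def _default(obj: Any):
    if isinstance(obj, np.ndarray):
        a = np.ascontiguousarray(obj)
        return {
            "__ndarray__": True,
            "dtype": a.dtype.str,
            "shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode("ascii"),
        }
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize object of type {type(obj)!r}")


def _object_hook(d: dict) -> Any:
    if d.get("__ndarray__"):
        raw = base64.b64decode(d["data"])
        return np.frombuffer(raw, dtype=np.dtype(d["dtype"])).reshape(d["shape"]).copy()
    return d


def encode_message(obj: dict) -> bytes:
    payload = json.dumps(obj, default=_default, allow_nan=True).encode("utf-8")
    return _HDR.pack(len(payload)) + payload


def decode_message(buf: bytes) -> dict:
    return json.loads(buf.decode("utf-8"), object_hook=_object_hook)


class Publisher:
    """Non-blocking fan-out of aggregate snapshots to TCP subscribers."""

    def __init__(self, host: str = "127.0.0.1", port: int = 0,
                 queue_depth: int = 4) -> None:
        self._srv = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._srv.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._srv.bind((host, port))
        self._srv.listen(16)
        self._srv.settimeout(0.2)
        self.address = self._srv.getsockname()
        self._queue_depth = queue_depth
        self._subs: list[tuple[queue.Queue, threading.Thread]] = []
        self._lock = threading.Lock()
        self._closed = threading.Event()
        self.n_published = 0
        self.n_dropped_messages = 0
        self._accept_thread = threading.Thread(
            target=self._accept_loop, name="publisher-accept", daemon=True)
        self._accept_thread.start()

    # -- internals --------------------------------------------------------

    def _accept_loop(self) -> None:
        while not self._closed.is_set():
            try:
                conn, _ = self._srv.accept()
            except socket.timeout:
                continue
            except OSError:
                return
            q: queue.Queue = queue.Queue(maxsize=self._queue_depth)
            t = threading.Thread(target=self._send_loop, args=(conn, q),
                                 name="publisher-send", daemon=True)
            t.start()
            with self._lock:
                self._subs.append((q, t))

    def _send_loop(self, conn: socket.socket, q: queue.Queue) -> None:
        conn.settimeout(5.0)
        try:
            while not self._closed.is_set():
                try:
                    msg = q.get(timeout=0.2)
                except queue.Empty:
                    continue
                if msg is None:
                    return
                conn.sendall(msg)
        except OSError:
            pass  # subscriber vanished; sender exits, master unaffected
        finally:
            try:
                conn.close()
            except OSError:
                pass

    # -- API ---------------------------------------------------------------

    @property
    def n_subscribers(self) -> int:
        with self._lock:
            return sum(t.is_alive() for _, t in self._subs)

    def publish(self, aggregate: dict) -> None:
        """Queue a snapshot for every live subscriber; never blocks.

        Zero subscribers is not an error; a full per-subscriber queue drops
        that subscriber's oldest pending snapshot.  Serialization failures
        are recorded and swallowed so the run continues.
        """
        try:
            msg = encode_message(aggregate)
        except TypeError:
            self.n_dropped_messages += 1
            return
        self.n_published += 1
        with self._lock:
            subs = list(self._subs)
        for q, t in subs:
            if not t.is_alive():
                continue
            while True:
                try:
                    q.put_nowait(msg)
                    break
                except queue.Full:
                    try:
                        q.get_nowait()  # drop oldest for this slow subscriber
                        self.n_dropped_messages += 1
                    except queue.Empty:
                        pass

    def close(self) -> None:
        self._closed.set()
        with self._lock:
            for q, _ in self._subs:
                try:
                    q.put_nowait(None)
                except queue.Full:
                    pass
        try:
            self._srv.close()
        except OSError:
            pass


class Subscriber:
    """A blocking client that receives aggregate snapshots from a Publisher."""

    def __init__(self, host: str, port: int, timeout: float = 5.0) -> None:
        self._sock = socket.create_connection((host, port), timeout=timeout)
        self._sock.settimeout(timeout)

    def recv(self) -> dict:
        """Receive the next snapshot (raises socket.timeout / OSError on loss)."""
        hdr = self._recv_exact(_HDR.size)
        (length,) = _HDR.unpack(hdr)
        return decode_message(self._recv_exact(length))

    def _recv_exact(self, n: int) -> bytes:
        chunks = []
        while n > 0:
            chunk = self._sock.recv(n)
            if not chunk:
                raise ConnectionError("publisher closed the connection")
            chunks.append(chunk)
            n -= len(chunk)
        return b"".join(chunks)

    def close(self) -> None:
        try:
            self._sock.close()
        except OSError:
            pass
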