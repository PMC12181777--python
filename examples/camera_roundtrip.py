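"""Capture-on-message camera service round trip.

Starts the TCP capture server backed by a synthetic bead scene, sends a few
serialized capture requests, and shows the acknowledged PNG files plus the
CSV index the server maintains — the full instrument-control loop without
any hardware.
"""

import tempfile
from pathlib import Path

from beadsim import (
    CameraModel,
    CameraServer,
    CaptureMessage,
    CaptureService,
    MockCameraSource,
    WellScene,
    render_frame,
    send_message,
)

out_dir = Path(tempfile.mkdtemp(prefix="beadsim_captures_"))
frame = render_frame(WellScene(opacity=0.8), CameraModel(seed=1))
service = CaptureService(MockCameraSource(frame), out_dir)
server = CameraServer(("127.0.0.1", 0), service)
server.start_background()
endpoint = server.server_address
print(f"camera server listening on {endpoint[0]}:{endpoint[1]}")

for i, well in enumerate(["A1", "A2", "A3"]):
    ack = send_message(endpoint, CaptureMessage("demo", well, 1, 30.0 * i, i))
    print(f"  sent request for {well} -> {ack}")

server.shutdown()
files = sorted(p.name for p in out_dir.glob("*.png"))
print(f"saved frames: {files}")
print(f"index file: {out_dir / 'index.csv'}")
# One PNG and one index row per acknowledged message; PNGs are lossless.
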