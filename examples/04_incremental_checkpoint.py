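"""Add samples to an existing analysis without re-searching the rest.

Search results are checkpointed under the SHA-256 of each sample file's
bytes.  A rerun with two extra proteomes re-searches only those two; a
renamed file is recognised by content and served from the checkpoint.
The final hit collection is identical to a from-scratch run.
"""

import shutil
import tempfile
from pathlib import Path

from markerphylo import SimulationSpec, simulate_dataset
from markerphylo.orthology import Checkpoint, checkpoint_diff, hash_file, params_fingerprint
from markerphylo.pipeline import RunConfig, run_align

out = Path(tempfile.mkdtemp())
spec = SimulationSpec(n_taxa=8, n_markers=10, marker_length=100, n_decoys=2, seed=8)
data = simulate_dataset(spec, out / "sim")
inputs = sorted(data["samples"].values())

# first pass: six samples
cfg = RunConfig(marker_dir=data["marker_dir"], inputs=inputs[:6], output_dir=out / "run")
run_align(cfg)
ckpt = Checkpoint.load(out / "run" / "checkpoint.jsonl")
print(f"first run:  searched {len(ckpt.entries)} samples")

# second pass: all eight — only the two new files get searched
hashes = {p.stem: hash_file(p) for p in inputs}
diff = checkpoint_diff(ckpt, hashes, ckpt.params_fingerprint)
print(f"second run: {len(diff.reusable)} reusable, {len(diff.to_search)} to search")
cfg2 = RunConfig(marker_dir=data["marker_dir"], inputs=inputs, output_dir=out / "run")
msas, ckpt2 = run_align(cfg2)
print(f"checkpoint now holds {len(ckpt2.entries)} samples; "
      f"{len(msas)} marker alignments built")

# a renamed, byte-identical file is still recognised
renamed = out / "renamed_sample.faa"
shutil.copy(inputs[0], renamed)
diff = checkpoint_diff(ckpt2, {"renamed_sample": hash_file(renamed)}, ckpt2.params_fingerprint)
print(f"renamed copy of {inputs[0].name}: classified "
      f"{'reusable' if diff.reusable else 'new'} (content hash, not file name)")
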