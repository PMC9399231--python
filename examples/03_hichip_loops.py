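"""HiChIP loop calling with a distance-decay background.

Bins simulated paired-end tags at 1 kb, fits a monotone distance-decay
expectation with per-anchor coverage bias, flags bin pairs whose Poisson
upper tail survives BH adjustment, classifies loops by their anchors
(enhancer vs promoter), and tests loops for differential contact between
conditions.
"""

import tempfile
from pathlib import Path

from shearmap.pipeline import Pipeline, PipelineConfig
from shearmap.synthetic import SynthConfig, read_truth

tmp = Path(tempfile.mkdtemp(prefix="shearmap_example_"))
pipe = Pipeline(PipelineConfig(data_dir=str(tmp / "data"), outdir=str(tmp / "out"), seed=1))
pipe.simulate(SynthConfig(seed=1))

loops, summary = pipe.loops()
print(f"{summary['n_loops']} loops at q < 0.01; classes: {summary['loop_classes']}")
print(f"{summary['n_gained']} gained and {summary['n_lost']} lost with LSS "
      f"at BH-adjusted p < 0.1")

truth = read_truth(pipe.cfg.data_dir)
called = set(zip(loops["bin1"].astype(int), loops["bin2"].astype(int)))
recall = len(called & truth.planted_loops) / len(truth.planted_loops)
print(f"planted enhancer-promoter loops recovered: {recall:.2f} "
      f"of {len(truth.planted_loops)}")
print("(a gained EP loop means an enhancer contacts its target promoter "
      "more often under laminar shear stress)")
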