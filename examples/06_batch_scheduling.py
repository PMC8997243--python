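"""Balance a batch of analysis jobs across CPU cores.

Per-video runtimes are estimated by timing a few probe-frame detections and
extrapolating; the longest-processing-time greedy rule then packs the jobs
so no core idles while work remains (makespan within 4/3 of optimal).
"""

from contourpose import DetectionParams, balance_jobs, estimate_duration
from contourpose.synthetic import make_crawler

seq, _ = make_crawler(T=60, seed=0)
params = DetectionParams(min_major=40, max_major=80)
per_video = estimate_duration(seq, params, n_probe=3)
print(f"estimated runtime for one {len(seq)}-frame video: {per_video:.1f} s")

durations = [per_video * k for k in (1.0, 2.5, 0.8, 1.6, 1.2, 3.0)]
assignment, makespan = balance_jobs(durations, n_cores=2)
for core, jobs in enumerate(assignment):
    load = sum(durations[j] for j in jobs)
    print(f"core {core}: jobs {jobs}, load {load:.1f} s")
print(f"makespan {makespan:.1f} s vs {sum(durations):.1f} s serial")
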