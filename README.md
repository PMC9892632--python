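# soothe

A closed-loop music-therapy recommender. `soothe` is aimed at digital
therapeutics researchers who want a fully inspectable reference
implementation of the classic adaptive music-selection loop: a
heart-rate biofeedback controller decides *how soothing* the next
piece of music should be, and a hybrid recommender decides *which*
piece at that level fits the patient's taste. Because no public
dataset exists for this setting, the package ships a first-class
synthetic-data module that plants known, recoverable structure, so
every component is testable end to end.

## The model

**Content side.** Track text (title / lyrics fragments / tags) is
weighted with TF-IDF,

```
TF(x,y) = f(x,y) / Σ_k f(k,y)        IDF(x) = log10(Q / q(x))
```

L2-normalized per track and stacked into a tracks × terms preference
matrix. A patient's profile is the normalized sum of their liked
tracks' rows; the content score of a candidate is the cosine.

**Collaborative side.** From the liked-track sets `Q(u)` and their
inverted index `Q(y)`:

```
user  similarity:  Z_uv = |Q(u) ∩ Q(v)| / sqrt(|Q(u)| |Q(v)|)
item  similarity:  Z_hy = |Q(h) ∩ Q(y)| / sqrt(|Q(h)| |Q(y)|)
popularity penalty: each co-liked item a contributes 1 / log10(1 + |Q(a)|)
user CF:  G(u,y) = Σ_{v ∈ S(u,K) ∩ Q(y)} Z_uv R_vy
item CF:  G(u,y) = Σ_{h ∈ Q(u) ∩ S(y,K)} Z_hy R_uh
```

with `S(·,K)` the K-nearest neighborhood (deterministic id tie-break)
and `R` implicit binary ratings. Item similarities may equivalently be
built from a user-by-user co-occurrence count matrix; both paths agree
exactly.

**Fusion.** `G = β · content + (1 − β) · CF`, `β ∈ [0, 1]`, after
min-max normalizing both score sets over the candidate pool; `β = 1`
and `β = 0` reproduce the pure rankings exactly.

**Controller.** Two heart-rate thresholds `θ_low < θ_high` map each
sample to an emotion state and a soothing level — above the high
threshold: excited → highly soothing music; below the low threshold:
relaxed → gently soothing; the closed band between them: normal →
moderately soothing. A session replays a trace, restricting each
step's playlist to the dictated level.

See `docs/methods.md` for assumptions, defaults, numerical choices and
limitations.

## Worked example

Generate a synthetic cohort (40 patients, 30 tracks, block affinity
0.9, a relaxed→normal→excited heart-rate schedule), then ask for a
playlist:

```
$ soothe --seed 7 synth --out-dir demo
$ soothe --seed 7 recommend --tracks demo/tracks.json \
    --interactions demo/interactions.csv --patient p003 --beta 0.5 --k 5
{
 "cold_start": false,
 "items": [
  {"score": 1.0,                 "track_id": "t009"},
  {"score": 0.26998955192209223, "track_id": "t001"},
  {"score": 0.1617019017024665,  "track_id": "t004"},
  {"score": 0.16017279897256087, "track_id": "t010"},
  {"score": 0.16010189580726764, "track_id": "t013"}
 ],
 "patient": "p003"
}
```

Patient `p003`'s planted preference block is *relaxed*
(`demo/ground_truth.json`), and the clear winner `t009` is indeed a
relaxed-category track the patient has not heard: both engines agree
on it, so its fused score hits the top of the min-max scale (1.0)
while the next candidates trail far behind. Now run the closed loop
over the generated 180-second trace with thresholds (72, 95) bpm:

```
$ soothe --seed 7 session --tracks demo/tracks.json \
    --interactions demo/interactions.csv --trace demo/trace.csv \
    --patient p003 --theta-low 72 --theta-high 95 --out demo/session.jsonl
INFO soothe: session: 180 steps, 6 level switches
$ head -2 demo/session.jsonl
{"config_hash": "a3d2be1c8054", "patient": "p003", "seed": 7, "tool_version": "0.1.0"}
{"hr_bpm": 59.99816299498946, "level_available": true, "soothing_level": "gentle",
 "state": "relaxed", "time_s": 0.0, "track_id": "t009"}
```

The trace starts in the relaxed band (≈ 60 bpm < 72), so the
controller prescribes gently soothing music and plays `t009`; the six
level switches are the noise-induced crossings around the two
thresholds as the schedule steps through its three states.

Survey count tables are summarized with half-up rounding to one
decimal:

```
$ soothe summarize-survey --counts counts.csv
group    very_satisfied_pct  satisfied_pct  dissatisfied_pct
Patient  59.3                28.7           12
```

Every subcommand is a thin wrapper over the library
(`soothe.corpus`, `soothe.collaborative`, `soothe.hybrid`,
`soothe.biofeedback`, `soothe.synthetic`, `soothe.evaluation`,
`soothe.io`), which is the intended API for scripted use.

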