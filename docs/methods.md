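# Methods

`soothe` models a closed-loop music-therapy session for chemotherapy
patients: a wearable heart-rate sensor stands in for emotional state, a
two-threshold controller maps that state to a soothing-level
prescription, and a hybrid recommender selects tracks at that level
from the patient's taste profile and the cohort's listening histories.
This note records the model, its assumptions, the defaults, and the
numerical and design choices that were genuinely open.

## Content model

Each track carries free text (title, lyrics fragments, tags). Terms are
tokenized (lowercase, punctuation stripped, whitespace split, no
stemming — the simplest deterministic baseline) and weighted with
TF-IDF:

    TF(x, y)  = f(x, y) / Σ_k f(k, y)
    IDF(x)    = log10(Q / q(x))
    w(x, y)   = TF(x, y) · IDF(x)

with `Q` the number of tracks and `q(x)` the number of tracks
containing term `x`. Base-10 logarithms are used throughout the
package — also in the popularity penalty below — so the two weights
stay on one comparable scale. IDF is unsmoothed for a corpus-derived
vocabulary, where `q(x) ≥ 1` always holds; a term supplied externally
that the corpus has never seen takes `log10(Q / (1 + q(x)))` so the
function is total. Each track's weight vector is divided by its
Euclidean (L2) norm — the standard reading of the normalization — and
stacked into a tracks × terms preference matrix. An all-zero row
(empty text, or text consisting solely of ubiquitous terms with IDF 0)
is left all-zero and flagged degenerate rather than raising.

A patient's content profile is the L2-normalized sum of the rows of
their liked tracks; the content score of a candidate is the dot product
of two unit vectors with non-negative entries, hence a cosine in
[0, 1]. This construction is the package's own choice: nothing in the
underlying method pins down how the per-patient content preference is
derived from the track matrix, and the normalized-sum profile is the
conventional one.

## Collaborative filtering

Histories are implicit feedback: `Q(u)` is the set of tracks patient
`u` liked, `Q(y)` the audience of track `y` (the inverted index), and
ratings default to 1 for every stored pair (a CSV column may override
with values in [0, 5]).

User-user similarity is set cosine

    Z_uv = |Q(u) ∩ Q(v)| / sqrt(|Q(u)| · |Q(v)|)

The square root belongs to the cosine reading; the variant without it
is exposed via `sqrt_denominator=False` for completeness. The
popularity-penalized form replaces each co-liked item's unit
contribution by `1 / log10(1 + |Q(a)|)`, damping evidence from
ubiquitous tracks. Note the penalty factor exceeds 1 when an audience
is below 9, so the penalized similarity is bounded by 1 only in the
large-audience regime the penalty is designed for; the implementation
does not clip.

Item-item similarity comes in the asymmetric conditional form
`|Q(h) ∩ Q(y)| / |Q(h)|` and the symmetric penalized form
`|Q(h) ∩ Q(y)| / sqrt(|Q(h)| · |Q(y)|)`. The latter drives
recommendation; the former is provided because both appear in the
method's lineage. The co-occurrence path accumulates shared-audience
counts user by user from the forward histories and normalizes the
integer counts identically to the direct pairwise path, so the two
agree bit for bit, which the tests assert.

Neighborhood scores:

    user CF:  G(u, y) = Σ_{v ∈ S(u, K) ∩ Q(y)} Z_uv · R_vy
    item CF:  G(u, y) = Σ_{h ∈ Q(u) ∩ S(y, K)} Z_hy · R_uh

`S(·, K)` is the K-nearest neighborhood, similarity descending, ties
broken by ascending id, self excluded — the tie-break makes every
ranking deterministic across runs. The item-CF orientation (sum over
liked tracks inside the candidate's neighborhood, rating of the liked
track) is the standard one and the only orientation consistent with
the user-CF structure.

All equation-level sums run in a defined order (vocabulary order,
ascending ids) with scalar arithmetic, so an independent per-cell
recomputation reproduces identical floats; the test suite checks
equality exactly, not to a tolerance.

## Hybrid fusion

    G = β · P_content + (1 − β) · P_cf,   β ∈ [0, 1]

Content cosines live in [0, 1] while CF scores are unbounded sums, so
both candidate score sets are min-max normalized before fusion by
default (a constant set maps to 0.5 everywhere); without a shared
scale β is uninterpretable. β defaults to 0.5 — no principled value
exists, and the endpoints are what the tests pin down: β = 1 and β = 0
reproduce the pure content and pure CF rankings exactly. The
per-patient content preference entering the fusion is the scalar
per-(patient, track) cosine, not a matrix row. Candidates are the full
corpus minus the patient's history, optionally filtered to the
controller's current soothing level. A cold-start patient is ranked
purely by content against a uniform unit-norm profile and the list is
flagged.

## Biofeedback controller

Two thresholds `θ_low < θ_high` (both in 30–220 bpm) partition heart
rate into three bands mapped to (state, soothing level):

    hr > θ_high            → excited → high
    hr < θ_low             → relaxed → gentle
    θ_low ≤ hr ≤ θ_high    → normal  → moderate

The middle band is closed on both ends — the boundary semantics were
unspecified, and a closed band makes the classifier total with the
transitions landing exactly at the first bpm beyond each edge. The
controller is memoryless and uses instantaneous heart rate; a trailing
mean smoothing window and an AR(1) noise option exist for experiments,
both off by default, and hysteresis is deliberately not implemented.
Default thresholds (60, 100) bpm are fixtures, always configurable —
no canonical values exist. The heart-rate classifier is the reference
implementation of a pluggable state-provider interface, so another
affect sensor can drive the same loop.

`run_session` classifies each sample and asks the recommender for a
playlist restricted to the dictated level; since the store is static
within a session the playlist is computed once per level, making the
per-step decision identical to pointwise classification (asserted).
If the library lacks a level, the gap is logged and the unrestricted
pool is used for that step.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structure the pipeline is supposed to
recover, with defaults that are the package's reference study
conditions:

* **Library** — 30 tracks round-robin over the three categories, each
  category with 12 private tokens plus 8 shared ones; each track draws
  40 tokens, 70 % from its own pool. This makes within-category TF-IDF
  cosine exceed cross-category cosine on average (a Monte-Carlo test
  over 20 seeds), which is all the content engine needs.
* **Cohort** — 40 patients, each assigned a preferred category; likes
  are independent Bernoulli draws at probability 0.9 in-block and
  (1 − 0.9) out-of-block. At affinity 0.5 the draws are symmetric and
  carry no block signal — the null condition.
* **Physiology** — 1 Hz heart rate at state means (65, 80, 110) bpm
  with i.i.d. Gaussian sd 3, clipped to 30–220. With thresholds
  (72, 95) the Gaussian tail probabilities put per-sample
  classification accuracy near 0.995, comfortably above the 0.9 the
  tests require.

Seeds are mandatory and all generators are bit-reproducible;
independent substreams per generator keep the corpus, interaction and
trace draws decoupled.

What the generator does **not** emulate: real lyric vocabulary
statistics, rating noise, popularity skew (likes are exchangeable
within a block), temporal dynamics of listening, autocorrelated or
drifting heart rate (beyond the AR(1) option), or any clinical
outcome. Passing tests therefore demonstrate that the algorithms
recover the structure they are designed for — not that the system has
a therapeutic effect on real patients, which no desk-scale experiment
can show.

## Evaluation choices

Survey proportions are `100 · count / n_total` rounded half-up to one
decimal — half-up, not banker's rounding, because that is the
convention count tables of this kind print — and rendered without a
trailing `.0`. Recall@K uses an empirical random baseline: a uniform
random K-subset of the same candidate pool scored through the same
code path. Note a structural fact about small catalogs: a random
recommender over C candidates has expected recall@K = K/C regardless
of the relevant set, so with a 30-track catalog the baseline for
recall@10 is at least 1/3 and no engine — however perfect — can exceed
3× that baseline. On the reference cohort item-CF reaches recall ≈
0.99 against a baseline ≈ 0.45 (factor ≈ 2.2, z ≈ 46), i.e. recovery
is essentially perfect and the factor is capped by the catalog size,
not by the engine.

## Problem sizes

The reference conditions (40 × 30 cohort, 20 seeds, 180-sample traces,
50 × 50 interaction fixtures, ≤ 10-track × ≤ 30-term corpora for the
exact-equality oracles) are deliberately desk-scale: every quantity is
exhaustively checkable and the full suite plus the acceptance script
run in well under a minute.

## Known limitations

* The penalized user similarity is unbounded above on very sparse
  cohorts (see above); consumers ranking by it are unaffected, but it
  is not a cosine there.
* Degenerate tracks (empty or all-ubiquitous text) score 0 against
  every profile and can only be recommended by tie-break.
* Min-max normalization makes fused scores relative to the candidate
  pool: the same track can receive different fused scores under
  different category filters. Rankings within a pool are unaffected.
* Cold-start handling ignores `β` by design; there is no
  popularity-based fallback.
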