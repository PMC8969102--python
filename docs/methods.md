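# Methods

## Problem setting

Two tasks over the same inputs — a spontaneous-speech recording (picture
description) and its CHAT transcript per subject:

1. **Dementia detection**: binary classification, label 1 = Alzheimer's
   dementia (AD, the positive class), 0 = healthy control (HC).
2. **MMSE regression**: predict the Mini-Mental State Examination score
   (integer 0–30; 25–30 is considered normal).

## Audio front end

A recording is resampled to 16 kHz on load (mono, channel-averaged) and
converted to a Mel power spectrogram: FFT size 2048, hop 1024 samples
(~64 ms), Hann window, 224 Mel bands on the Slaney scale (linear below
1 kHz, logarithmic above, unit-area triangular filters). Power is
dB-scaled against the per-recording maximum and floored at −80 dB, making
digital silence well defined. Delta and delta-delta channels are the
first and second temporal derivatives estimated by 9-frame local linear
regression (Savitzky–Golay, order 1 — the standard delta-feature
estimator); an input therefore needs at least 9 frames. The three
channels are each resized to 224×224 by bilinear interpolation, min–max
scaled to [0, 1] per channel, and standardized with the image encoder's
expected mean/std (default 0.5/0.5). All of this is deterministic:
identical waveform in, bit-identical image out.

Sample rate, FFT size, dB reference/floor and delta window are
package conventions (configurable); the band count (224), hop (1024),
window (Hann) and 224×224 output are the fixed defaults of the modeled
pipeline. One image is built per full recording; no segmentation.

## Transcript front end

CHAT main-tier utterances of the configured speakers (default PAR only —
the patient's speech is the diagnostic object) are parsed in document
order; continuation lines are joined; dependent tiers (%mor, …) are
dropped. Inline annotation is stripped to plain words: bracketed codes
(`[/]`, `[: text]`, `[* err]`), retracing angle brackets, pause codes
`(.)`, events/fillers introduced by `&`, special-form suffixes (`word@x`),
shortening parentheses (`(be)cause` → `because`). Spoken word forms —
including repetitions — are kept, because disfluencies carry clinical
signal; utterance terminators survive as tokens. Malformed files fail
with a line-numbered parse error; a file without utterances for the
requested tiers yields an empty transcript.

Encoding uses a deterministic MD5-hashing tokenizer (vocabulary-free,
stable across processes): `[CLS]` + word ids + `[SEP]`, tail-truncated and
padded to exactly `max_len` (512 at full scale), with a boolean mask
marking real tokens. Truncation keeps the transcript head, the standard
choice for encoder models.

## Acoustic functionals

Each recording is summarized by an 88-dimensional vector of acoustic
functionals organized in the spirit of the extended Geneva minimalistic
parameter sets: ten frame-level descriptors (F0 in semitones above
27.5 Hz via autocorrelation, voicing strength, RMS energy in dB, spectral
centroid/slope/rolloff/flux, zero-crossing rate, low/high band ratio, a
harmonicity proxy) each summarized by eight statistics (mean, std, 10th/
50th/90th percentiles, range, slope mean/std), plus eight temporal
features (voiced fraction, voiced-segment rate and durations, silence
fraction, energy-peak rate, duration, overall RMS). The layout is fixed
and named; index 0 is mean F0 in semitones, so a 440 Hz tone scores
12·log₂(440/27.5) = 48. The set matches the 88-dimensional contract and
the semantics the fusion model relies on, but it is a native
implementation, not a bit-compatible re-creation of any specific toolkit's
feature values. Functionals require ≥ 1 s of audio.

For fusion, the 88-vector passes through a trainable linear map to 256
dimensions and is repeated once per text token, giving an acoustic
sequence aligned with the word sequence.

## Encoders

The fusion layers depend only on a contract: text encoder → N×d, image
encoder → T×d with the class-token summary at row 0, shared hidden size d.
At full replication scale these are BERT-base and ViT-B/16 (d = 768,
N = 512, T = 197); offline, `build_tiny_encoders` provides small
randomly-initialized pre-norm transformer encoders (default 2 blocks,
single-head attention, 4× feed-forward width — the standard transformer
ratio) that honor the same contract and are reproducible from a seed.
Pad keys are masked out of text-encoder attention by default, so pad
content cannot leak into real-token rows. The image encoder patchifies
the 3×S×S image on the most-square grid with T−1 patches whose sides
divide S (16×16 patches for T = 197 at S = 224).

## Fusion mechanisms

Sequences are stored tokens-by-features (N×d, T×d) everywhere; the
co-attention module transposes at its boundary to the d×N / d×T
orientation its equations use.

**Co-attention** (k = 40 by default): F = tanh(Cᵀ W_l S) ∈ ℝ^{N×T};
H_s = tanh(W_s S + (W_c C) F), H_c = tanh(W_c C + (W_s S) Fᵀ);
a_s = softmax(w_hsᵀ H_s) over the T patches, a_c = softmax(w_hcᵀ H_c)
over the N tokens; ŝ = Σ a_sⁱ sᵢ, ĉ = Σ a_cʲ cⱼ; p = [ŝ; ĉ]. Dropout 0.4
on p, dense 128 + ReLU, dropout 0.2, head. Pad positions are *not*
excluded from a_c by default (faithful to the modeled design); an
optional flag masks them.

**Multimodal shifting gate**: word embeddings e(i) come from a *frozen*
first text encoder. The image class vector (tiled N times) and the
projected acoustic vector (tiled N times) enter per-token sigmoid gates;
the gate output lives in the d-dimensional shift space (forced by the
element-wise product in the shift equation). h_m(i) = w_v(i)⊙(W_v h_v(i))
+ w_a(i)⊙(W_a h_a(i)) + b_m with a single bias vector shared across
positions (a per-position bias would be content-independent and tied to
position). α = min(β‖e(i)‖₂/(‖h_m(i)‖₂ + ε), 1) with ε = 1e-9 guarding
the zero-shift case and the cap making h_m = 0 an exact identity.
After layer norm then dropout 0.4, the shifted sequence feeds a second,
*trainable* text encoder initialized from the same weights; it adds its
own positional information. Its class-token output → dropout 0.2 → dense
128 + ReLU → head. β defaults: 0.01 (acoustic, both), 0.001 (visual).

**Gated self-attention** (d_g = 64 by default): Z = [X; Y] with text rows
first; Q = K = V = Z; M = σ(FC_g(FC_qg(Q) ⊙ FC_kg(K))) ∈ ℝ^{m×2}; its two
columns are tiled across the d features and modulate queries and keys;
A_g = softmax((Q⊙M̃_q)(K⊙M̃_k)ᵀ/√d) row-wise (over keys — the only
convention making H = A_g V an attention average); H is mean-pooled over
the m positions, dropout 0.3, dense 128 + ReLU, head. Single head, single
layer; pad positions unmasked by default with an optional masking flag.

Heads: classification ends in 2 logits (argmax decision, no threshold
tuning); regression ends in one ReLU unit, so predictions are ≥ 0 but not
clipped at 30 (an optional post-hoc clamp exists).

## Training protocol

Stratified 65/35 train/validation split (round-half-up on the train side;
largest-remainder allocation keeps the global size exact; stratification
by class guards against degenerate validation sets at small n). Adam with
learning rate 1e-5 by default — the fine-tuning rate appropriate for
pretrained encoders; from-scratch tiny encoders use larger rates (the
desk-scale experiments use 2e-3 for classification, 1e-3 for regression).
Reduce-on-plateau ×0.1 after 3 consecutive epochs without validation-loss
improvement; early stopping after 6; best-validation checkpoint restored.
Classification minimizes cross-entropy; regression minimizes RMSE, and
the regression head's output bias is initialized to the mean training
target so early epochs are not spent learning the score offset. Subjects
without an MMSE score are dropped for regression only. Repetitions (5 by
default) share the split and differ in model-initialization seed; metrics
are aggregated as mean ± *population* standard deviation. Batch size 8
(classification) / 4 (regression) at desk scale; configurable.

## Synthetic corpus generator

Emulates the *structure* of a balanced screening corpus, never its
content: one 16 kHz WAV + one CHAT file per subject and a metadata CSV
(`id,label,mmse`). MMSE is drawn per group — HC: round(clip(N(28, 1.2),
25, 30)); AD: round(clip(N(17, 2.5), 10, 24)), a moderate-stage band
consistent with typical AD cohort means — and a severity scalar
(30−MMSE)/20 derived from it drives three group effects: extra inter-
utterance pauses (pause_rate_delta = 1.5 at full severity), slowed
syllable rate (speech_rate_delta = 1.2 syll/s), and a shrunken word pool
with retraced repetitions (vocabulary_shrink = 0.5). Because severity
drives both the MMSE and the speech statistics, the regression target is
in principle recoverable from the signals. Setting all three deltas to 0
removes every group difference from the signals while keeping the
MMSE/group link — the null condition for calibration checks. Audio is
synthesized as harmonic syllable tones with envelopes and silences: it
carries pause/rate statistics an energy analysis can recover, but it is
*not* speech, and transcripts are templated picture-description
sentences. Passing tests on this corpus demonstrates that the pipeline,
architectures and protocol work end to end and that information flows
from both modalities; it says nothing about clinical performance on real
speech. Everything is deterministic from the corpus seed (byte-identical
files on re-generation).

## Numerical core

Tensors are float64 numpy arrays with reverse-mode autodiff (topological-
order accumulation; broadcast gradients summed back to operand shapes).
Softmax is computed with max-subtraction; the α cap uses a min-with-
constant whose gradient flows only below the cap; RMSE adds 1e-12 under
the square root to keep the gradient finite at zero error. Dropout is
inverted (scaled at train time, identity in eval). Gradients of every
operation are tested against central finite differences.

## Desk-scale problem sizes

Verification runs use: 24-subject corpora with 6 s recordings, tiny
encoders d = 32, N = 64 tokens, T = 17 patches, ≤ 50 epochs (fit
capability); five 114-subject null corpora with 4 s recordings and
d = 16, N = 32, T = 5, pooling 200 validation predictions (chance-level
check). Fusion-block oracle checks run 100 random instances with all
dimensions ≤ 6 against explicit index-loop implementations at 1e-6.

## Limitations

- The pretrained encoder grade (BERT-base / ViT-B/16 checkpoints) is an
  interface only; constructing it requires a deep-learning framework and
  checkpoint access not bundled here.
- The acoustic functionals follow the 88-dimension contract and
  semantics, not any toolkit's exact values.
- The CHAT parser covers the constructs common in picture-description
  transcripts, not the full CHAT grammar.
- Synthetic corpora validate mechanics, not clinical claims; silence in
  synthetic audio is cleaner than in field recordings, so energy-based
  statistics are easier to recover than they would be in practice.
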