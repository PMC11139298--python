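feature,category
F0semitoneFrom27.5Hz_sma3nz_amean,vocal folds
F0semitoneFrom27.5Hz_sma3nz_stddevNorm,vocal folds
F0semitoneFrom27.5Hz_sma3nz_percentile20.0,vocal folds
F0semitoneFrom27.5Hz_sma3nz_percentile50.0,vocal folds
F0semitoneFrom27.5Hz_sma3nz_percentile80.0,vocal folds
F0semitoneFrom27.5Hz_sma3nz_pctlrange0-2,vocal folds
F0semitoneFrom27.5Hz_sma3nz_meanRisingSlope,vocal folds
F0semitoneFrom27.5Hz_sma3nz_stddevRisingSlope,vocal folds
F0semitoneFrom27.5Hz_sma3nz_meanFallingSlope,vocal folds
F0semitoneFrom27.5Hz_sma3nz_stddevFallingSlope,vocal folds
jitterLocal_sma3nz_amean,vocal folds
jitterLocal_sma3nz_stddevNorm,vocal folds
shimmerLocaldB_sma3nz_amean,vocal folds
shimmerLocaldB_sma3nz_stddevNorm,vocal folds
loudness_sma3_amean,intensity
loudness_sma3_stddevNorm,intensity
loudness_sma3_percentile20.0,intensity
loudness_sma3_percentile50.0,intensity
loudness_sma3_percentile80.0,intensity
loudness_sma3_pctlrange0-2,intensity
loudness_sma3_meanRisingSlope,intensity
loudness_sma3_stddevRisingSlope,intensity
loudness_sma3_meanFallingSlope,intensity
loudness_sma3_stddevFallingSlope,intensity
HNRdBACF_sma3nz_amean,intensity
HNRdBACF_sma3nz_stddevNorm,intensity
alphaRatioV_sma3nz_amean,spectral balance
alphaRatioV_sma3nz_stddevNorm,spectral balance
hammarbergIndexV_sma3nz_amean,spectral balance
hammarbergIndexV_sma3nz_stddevNorm,spectral balance
slopeV0-500_sma3nz_amean,spectral balance
slopeV0-500_sma3nz_stddevNorm,spectral balance
slopeV500-1500_sma3nz_amean,spectral balance
slopeV500-1500_sma3nz_stddevNorm,spectral balance
spectralFlux_sma3_amean,spectral balance
spectralFlux_sma3_stddevNorm,spectral balance
spectralFluxV_sma3nz_amean,spectral balance
spectralFluxV_sma3nz_stddevNorm,spectral balance
mfcc1_sma3_amean,vocal tract
mfcc1_sma3_stddevNorm,vocal tract
mfcc2_sma3_amean,vocal tract
mfcc2_sma3_stddevNorm,vocal tract
mfcc3_sma3_amean,vocal tract
mfcc3_sma3_stddevNorm,vocal tract
mfcc4_sma3_amean,vocal tract
mfcc4_sma3_stddevNorm,vocal tract
mfcc1V_sma3nz_amean,vocal tract
mfcc1V_sma3nz_stddevNorm,vocal tract
mfcc2V_sma3nz_amean,vocal tract
mfcc2V_sma3nz_stddevNorm,vocal tract
mfcc3V_sma3nz_amean,vocal tract
mfcc3V_sma3nz_stddevNorm,vocal tract
mfcc4V_sma3nz_amean,vocal tract
mfcc4V_sma3nz_stddevNorm,vocal tract
logRelF0-H1-H2_sma3nz_amean,spectral balance
logRelF0-H1-H2_sma3nz_stddevNorm,spectral balance
logRelF0-H1-A3_sma3nz_amean,spectral balance
logRelF0-H1-A3_sma3nz_stddevNorm,spectral balance
F1frequency_sma3nz_amean,vocal tract
F1frequency_sma3nz_stddevNorm,vocal tract
F1bandwidth_sma3nz_amean,vocal tract
F1bandwidth_sma3nz_stddevNorm,vocal tract
F1amplitudeLogRelF0_sma3nz_amean,vocal tract
F1amplitudeLogRelF0_sma3nz_stddevNorm,vocal tract
F2frequency_sma3nz_amean,vocal tract
F2frequency_sma3nz_stddevNorm,vocal tract
F2bandwidth_sma3nz_amean,vocal tract
F2bandwidth_sma3nz_stddevNorm,vocal tract
F2amplitudeLogRelF0_sma3nz_amean,vocal tract
F2amplitudeLogRelF0_sma3nz_stddevNorm,vocal tract
F3frequency_sma3nz_amean,vocal tract
F3frequency_sma3nz_stddevNorm,vocal tract
F3bandwidth_sma3nz_amean,vocal tract
F3bandwidth_sma3nz_stddevNorm,vocal tract
F3amplitudeLogRelF0_sma3nz_amean,vocal tract
F3amplitudeLogRelF0_sma3nz_stddevNorm,vocal tract
alphaRatioUV_sma3nz_amean,spectral balance
hammarbergIndexUV_sma3nz_amean,spectral balance
slopeUV0-500_sma3nz_amean,spectral balance
slopeUV500-1500_sma3nz_amean,spectral balance
spectralFluxUV_sma3nz_amean,spectral balance
loudnessPeaksPerSec,intensity
VoicedSegmentsPerSec,prosody
MeanVoicedSegmentLengthSec,prosody
StddevVoicedSegmentLengthSec,prosody
MeanUnvoicedSegmentLength,prosody
StddevUnvoicedSegmentLength,prosody
equivalentSoundLevel_dBp,intensity
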