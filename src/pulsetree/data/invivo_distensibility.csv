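group,distensibility_insilico,distensibility_invivo_esrd,source
aorta,27.0,21.0,measured
carotid,23.0,18.0,measured
femoral,10.6,6.6,interpolated
tibial,9.0,5.0,interpolated
brachial,7.3,3.5,measured
radial,6.4,2.6,measured
coronary,6.1,4.5,interpolated
cerebral,8.1,4.1,interpolated
digital,5.3,3.4,interpolated
dorsal,5.7,3.2,interpolated
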