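patient_id,schedule_id,dose_mg,interval_h,time_h,dlt
P01,weekly,20.0,168.0,504.0,0
P02,weekly,20.0,168.0,504.0,0
P03,weekly,20.0,168.0,504.0,0
P04,weekly,20.0,168.0,504.0,0
P05,weekly,20.0,168.0,504.0,0
P06,weekly,30.0,168.0,360.0,1
P07,weekly,30.0,168.0,360.0,1
P08,weekly,30.0,168.0,360.0,1
P09,weekly,30.0,168.0,360.0,1
P10,weekly,30.0,168.0,504.0,0
P11,weekly,30.0,168.0,504.0,0
P12,weekly,30.0,168.0,504.0,0
P13,weekly,30.0,168.0,504.0,0
P14,weekly,30.0,168.0,504.0,0
P15,weekly,30.0,168.0,504.0,0
P16,weekly,30.0,168.0,504.0,0
P17,weekly,30.0,168.0,504.0,0
P18,weekly,30.0,168.0,504.0,0
P19,daily,2.5,24.0,360.0,1
P20,daily,2.5,24.0,360.0,1
P21,daily,2.5,24.0,504.0,0
P22,daily,2.5,24.0,504.0,0
P23,daily,5.0,24.0,360.0,1
P24,daily,5.0,24.0,360.0,1
P25,daily,5.0,24.0,360.0,1
P26,daily,5.0,24.0,504.0,0
P27,daily,5.0,24.0,504.0,0
P28,daily,5.0,24.0,504.0,0
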