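sample_id,group,age,sex,location,dysplasia,size_cm,histology,signal_score,gas_score,protein17_score
CT01,control,55,Female,,,,,0.05,0.12,0.08
CT02,control,61,Male,,,,,0.11,0.07,0.15
CT03,control,48,Female,,,,,0.02,0.21,0.03
CT04,control,67,Male,,,,,0.27,0.16,0.22
CT05,control,59,Female,,,,,0.08,0.34,0.11
CT06,control,72,Male,,,,,0.19,0.09,0.41
CT07,control,63,Female,,,,,0.04,0.27,0.06
CT08,control,51,Male,,,,,0.33,0.05,0.18
CT09,control,69,Female,,,,,0.14,0.41,0.09
CT10,control,57,Male,,,,,0.06,0.18,0.27
CT11,control,64,Female,,,,,0.22,0.80,0.13
CT12,control,53,Male,,,,,0.01,0.23,0.05
CT13,control,70,Female,,,,,0.41,0.11,0.31
CT14,control,46,Male,,,,,0.09,0.06,0.02
CT15,control,66,Female,,,,,0.17,0.38,0.19
CT16,control,58,Male,,,,,0.03,0.15,0.36
CT17,control,74,Female,,,,,0.29,0.29,0.07
CT18,control,50,Male,,,,,0.12,0.02,0.24
CT19,control,62,Female,,,,,0.07,0.46,0.12
CT20,control,68,Male,,,,,0.24,0.19,0.04
CT21,control,56,Female,,,,,0.16,0.74,0.29
CT22,control,71,Male,,,,,0.02,0.08,0.16
CT23,control,49,Female,,,,,0.36,0.31,0.01
CT24,control,65,Male,,,,,0.13,0.13,0.33
CT25,control,60,Female,,,,,0.05,0.25,0.21
CT26,control,76,Male,,,,,0.21,0.04,0.08
CT27,control,54,Female,,,,,0.10,0.36,0.14
CT28,control,73,Male,,,,,0.30,0.10,0.26
CT29,control,47,Female,,,,,0.01,0.43,0.05
CT30,control,69,Male,,,,,0.18,0.22,0.38
CT31,control,52,Female,,,,,0.26,0.17,0.10
CT32,control,80,Male,,,,,0.08,0.30,0.17
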