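sample_id,group,age,sex,location,dysplasia,size_cm,histology,signal_score,gas_score,protein17_score
AA01,case,59,Female,Rectum,High grade/severe,5.3,Tubular,0.96,0.75,0.17
AA02,case,63,Male,Sigmoid colon,Low,2.1,Tubulovillous,0.96,0.61,0.02
AA03,case,71,Male,Cecum,Low,4,Tubular,0.94,0.4,0.37
AA04,case,63,Male,Cecum,Low,1.6,Tubular,0.94,1,0.99
AA05,case,46,Female,Rectum,Low,4,Tubular,0.92,0.99,0.92
AA06,case,65,Male,Cecum,Low,2.5,Tubulovillous,0.92,0.98,1
AA07,case,74,Female,Cecum,Low,1.5,Tubular,0.85,0.99,0.8
AA08,case,52,Female,Rectum,Low,2.6,Tubular,0.82,0.83,0.78
AA09,case,66,Male,Cecum,Low,1.2,Tubular,0.79,0.78,0.43
AA10,case,56,Male,Ascending colon,Low,3.5,Tubular,0.63,0.29,0.04
AA11,case,65,Male,Hepatic flexure,Not available,2.5,Tubular,0.61,0.72,0.43
AA12,case,56,Male,Rectum,High grade/severe,6,Tubulovillous,0.6,0.92,0.3
AA13,case,60,Female,Transverse colon,Low,1.3,Tubular,0.52,0.54,0.25
AA14,case,64,Female,Transverse colon,Low,1,Tubular,0.47,0.07,0.52
AA15,case,52,Female,Ascending colon,High grade/severe,3.2,Tubular,0.45,0.39,0.96
AA16,case,72,Male,Cecum,High grade/severe,2,Tubular,0.41,0.15,0.27
AA17,case,67,Female,Cecum,Low,4.5,Tubulovillous,0.37,0.21,0.26
AA18,case,71,Female,Ascending colon,Low,3.2,Tubular,0.32,0.05,0.15
AA19,case,75,Male,Cecum,Low,1,Tubular,0.29,0.09,0.08
AA20,case,50,Female,Cecum,High grade/severe,4.5,Tubulovillous,0.26,0.67,0.99
AA21,case,61,Female,Rectum,Low,2.8,Villous adenoma,0.25,0.98,0.79
AA22,case,59,Female,Cecum,Low,1.2,Tubular,0.25,0.25,0.36
AA23,case,67,Male,Transverse colon,Low,1,Tubular,0.24,0.22,0.26
AA24,case,47,Female,Cecum,High grade/severe,5.2,Tubulovillous,0.22,0.29,0.22
AA25,case,50,Male,Sigmoid colon,Low,1.8,Tubular,0.18,0.37,0.04
AA26,case,53,Male,Descending colon,Low,2,Tubular,0.17,1,0.59
AA27,case,72,Female,Ascending colon,Not available,3,Tubular,0.16,0.42,0.36
AA28,case,80,Male,Cecum,High grade/severe,3,Tubular,0.15,0.44,0.99
AA29,case,71,Female,Cecum,Low,2,Serrated adenoma,0.15,0.35,0.08
AA30,case,37,Male,Cecum,Low,1.5,Serrated adenoma,0.12,0.2,0.11
AA31,case,78,Male,Transverse colon,Low,1.8,Tubulovillous,0.1,0.25,0.06
AA32,case,67,Female,Ascending colon,Low,3,Serrated adenoma,0.09,0.17,0.06
AA33,case,69,Male,Cecum,Low,4,Tubulovillous,0.09,0.19,0.87
AA34,case,76,Female,Cecum,Low,3,Tubular,0.07,0.15,0.12
AA35,case,68,Female,Rectum,Low,2.5,Villous adenoma,0.07,0.55,0.57
AA36,case,72,Female,Ascending colon,Low,2.5,Tubulovillous,0.05,0.58,0.93
AA37,case,65,Female,Hepatic flexure,Low,1.2,Serrated adenoma,0.03,0.18,0.21
AA38,case,68,Female,Cecum,High grade/severe,2.5,Tubular,0.02,0.26,0.27
AA39,case,74,Female,Cecum,Low,4,Tubular,0.01,0.05,0.92
AA40,case,72,Female,Hepatic flexure,Low,1.5,Serrated adenoma,0.01,0.13,0.13
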