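theta_deg,radius_mm,height_mm
0.0,6.065764148230464,0.0
22.5,5.5040904046367345,0.0210094916046791
45.0,5.016099799494988,0.05544438074738156
67.5,4.592126214433022,0.09781045967079949
90.0,4.22377158027345,0.14631859800814864
112.5,3.9037395280714233,0.19997400721832773
135.0,3.6256908626316062,0.2581233505839061
157.5,3.384117995723703,0.32029694718663343
180.0,3.1742358517695366,0.3861370951299023
202.5,2.9918870850614314,0.455360186768271
225.0,2.833459731054469,0.5277345689470786
247.5,2.6958156605693366,0.6030666363734435
270.0,2.5762284197265495,0.6811916061013386
292.5,2.4723292243454056,0.7619671292065971
315.0,2.3820600390646725,0.8452687112183415
337.5,2.3036328117761915,0.93098633399964
360.0,2.2354940558870107,1.0190219033335435
382.5,2.1762940788554723,1.1092872805284995
405.0,2.1248602474800573,1.201702737383512
427.5,2.0801737603798127,1.2961957246537583
450.0,2.0413494675756247,1.392699877027987
472.5,2.007618337438589,1.4911541994905364
495.0,1.9783122237107709,1.5915023948359182
517.5,1.9528506308634914,1.6936923024721648
540.0,1.9307292156413407,1.7976754260056191
562.5,1.911509797030494,1.9034065324098355
585.0,1.8948116767687722,2.0108433094740334
607.5,1.8803040984741006,2.119946071120838
630.0,1.867699696021778,2.2306775023628207
652.5,1.8567488013960038,2.3430024373284843
675.0,1.8472344992655834,2.4568876650679616
697.5,1.8389683303248403,2.5723017588444006
720.0,1.8317865582915105,2.6892149253989244
742.5,1.8255469266183062,2.8075988712964555
765.0,1.8201258406750918,2.927426683954211
787.5,1.8154159195863322,3.0486727253525316
810.0,1.811323869230608,3.171312536749972
832.5,1.807768634270569,3.295322752987381
855.0,1.8046797926087352,3.4206810251812767
877.5,1.801996160466522,3.5473659507847515
900.0,1.7996645804558964,3.6753570101417314
922.5,1.7976388686377833,3.804634508783555
945.0,1.795878899710557,3.9351795248199704
967.5,1.7943498122080281,4.066973860863555
990.0,1.7930213179634877,4.2
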