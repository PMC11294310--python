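kernel,qir,criterion,level,median,iqr_lo,iqr_hi
Qr44,2,noise,popliteal,4,4,4
Qr44,2,noise,btk,4,4,4
Qr44,2,delineation,popliteal,3,2,3
Qr44,2,delineation,btk,2,2,3
Qr44,2,overall,popliteal,3,3,4
Qr44,2,overall,btk,3,3,3
Qr44,3,noise,popliteal,5,4,5
Qr44,3,noise,btk,5,4,5
Qr44,3,delineation,popliteal,3,2,3
Qr44,3,delineation,btk,2,2,3
Qr44,3,overall,popliteal,3,3,3
Qr44,3,overall,btk,3,3,3
Qr44,4,noise,popliteal,5,5,5
Qr44,4,noise,btk,5,5,5
Qr44,4,delineation,popliteal,3,2,3
Qr44,4,delineation,btk,2,2,3
Qr44,4,overall,popliteal,3,3,4
Qr44,4,overall,btk,3,3,3
Qr60,2,noise,popliteal,3,3,3
Qr60,2,noise,btk,3,3,3
Qr60,2,delineation,popliteal,4,3,4
Qr60,2,delineation,btk,4,3,4
Qr60,2,overall,popliteal,4,3,4
Qr60,2,overall,btk,3,3,4
Qr60,3,noise,popliteal,3,3,4
Qr60,3,noise,btk,3,3,4
Qr60,3,delineation,popliteal,4,4,5
Qr60,3,delineation,btk,4,4,4
Qr60,3,overall,popliteal,4,4,4
Qr60,3,overall,btk,4,4,4
Qr60,4,noise,popliteal,4,4,4
Qr60,4,noise,btk,4,4,4
Qr60,4,delineation,popliteal,5,4,5
Qr60,4,delineation,btk,4,4,5
Qr60,4,overall,popliteal,5,4,5
Qr60,4,overall,btk,4,4,5
Qr72,2,noise,popliteal,1,1,2
Qr72,2,noise,btk,1,1,2
Qr72,2,delineation,popliteal,2,2,3
Qr72,2,delineation,btk,2,2,3
Qr72,2,overall,popliteal,2,2,2
Qr72,2,overall,btk,2,2,2
Qr72,3,noise,popliteal,2,1,2
Qr72,3,noise,btk,2,1,2
Qr72,3,delineation,popliteal,3,2,3
Qr72,3,delineation,btk,2,2,3
Qr72,3,overall,popliteal,2,2,3
Qr72,3,overall,btk,2,2,3
Qr72,4,noise,popliteal,2,2,3
Qr72,4,noise,btk,2,2,3
Qr72,4,delineation,popliteal,3,2,3
Qr72,4,delineation,btk,3,2,3
Qr72,4,overall,popliteal,3,2,3
Qr72,4,overall,btk,3,2,3
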